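"""Paired-stream adversarial CNN for group discrimination on TF/topo maps.

A shared feature extractor ``f`` (the Base CNN) is applied to the baseline
matrix ``B_ts`` and the post-session matrix ``A_ts`` of the same subject
and timepoint; the difference ``d = f(A) - f(B)`` feeds two heads:

* the group head ``h_t`` (Top NN) predicting CON vs EXE, and
* a subject head ``h_s`` (the adversary) predicting which of the S
  subjects the tuple came from.

In ``tf`` mode every convolution and pooling kernel extends only along the
frequency axis (extent 1 along electrodes), because frequency is ordered
while electrode index is not; in ``topo`` mode ordinary 2D convolutions
are used on stacked scalp frames.

Training alternates per minibatch between (i) the adversary minimizing its
own negative log-likelihood J_s with the extractor frozen, and (ii) the
extractor and group head minimizing the domain-confusion objective

    J_f = J_g + lambda * sum_i KL(U || h_s(f(x_i))),

where U is the uniform distribution over subjects.  Driving the adversary's
output toward uniform removes subject-identity information from the
features, which is what lets the group head generalize to held-out
subjects when the cohort is small.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .tfmaps import PairDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ArchConfig", "TrainConfig", "ModelBundle", "TrainHistory", "SplitPlan",
    "build_models", "forward_pair", "losses", "train", "make_split",
    "evaluate", "select_lambda", "extract_features",
    "feature_behavior_correlation", "kl_from_uniform",
]


@dataclass(frozen=True)
class ArchConfig:
    """Layer geometry for the Base CNN and the two heads."""

    mode: str = "tf"  # "tf" (electrodes x freqs) or "topo" (k x H x W)
    conv_channels: tuple[int, ...] = (8,)
    kernel_freq: int = 5       # filter extent along frequency (tf) / both axes (topo)
    kernel_electrode: int = 1  # must stay 1 in tf mode
    pool: int | tuple[int, ...] = 1  # per-block pooling (int = same for all)
    embed: tuple[int, ...] = (64,)  # dense tail of the Base CNN (part of theta_f)
    head_hidden: tuple[int, ...] = (32, 16)

    def __post_init__(self):
        if self.mode not in ("tf", "topo"):
            raise ValueError("mode must be 'tf' or 'topo'")
        if self.mode == "tf" and self.kernel_electrode != 1:
            raise ValueError(
                "tf mode convolves along frequency only; electrode kernel extent must be 1")

    @property
    def pools(self) -> tuple[int, ...]:
        if isinstance(self.pool, int):
            return (self.pool,) * len(self.conv_channels)
        if len(self.pool) != len(self.conv_channels):
            raise ValueError("one pool factor per conv block required")
        return tuple(self.pool)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 12
    batch_size: int = 128
    lr: float = 1e-3
    val_eval_cap: int = 4000   # max validation tuples scored per epoch (deterministic head)
    adversary_steps: int = 1   # adversary updates per main update
    keep_best: bool = False    # restore the epoch with lowest validation J_g


@dataclass
class TrainHistory:
    """Per-epoch mean losses and validation accuracies."""

    J_g: list[float] = field(default_factory=list)
    J_s: list[float] = field(default_factory=list)
    kl: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    val_acc_group: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class SplitPlan:
    """Fold assignments (and optional control label shuffles) for training."""

    strategy: str
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, val_idx) flat tuple indices
    y_group_subject: np.ndarray | None = None   # per-subject override (subject-level shuffle)
    y_group_tuple: np.ndarray | None = None     # per-tuple override (timepoint-level shuffle)

    def labels_for(self, dataset: PairDataset, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.intp)
        if self.y_group_tuple is not None:
            return self.y_group_tuple[idx]
        if self.y_group_subject is not None:
            return self.y_group_subject[dataset.subject_of(idx)]
        return dataset.y_group[dataset.subject_of(idx)]


class ModelBundle:
    """Parameters of the feature extractor and both heads, plus metadata."""

    def __init__(self, arch: ArchConfig, S: int, lam: float, seed: int,
                 input_shape: tuple[int, ...], dtype=np.float32):
        if S < 2:
            raise ValueError("need at least 2 subjects")
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        self.arch = arch
        self.S = S
        self.lam = float(lam)
        self.seed = int(seed)
        self.input_shape = tuple(input_shape)
        self.dtype = np.dtype(dtype)
        self.trained = False
        rng = np.random.default_rng(seed)
        self.conv_params: list[tuple[Tensor, Tensor]] = []
        if arch.mode == "tf":
            n_elec, n_freq = input_shape
            in_ch, length = 1, n_freq
            for out_ch, pool in zip(arch.conv_channels, arch.pools):
                w = Tensor((rng.standard_normal((out_ch, in_ch, arch.kernel_freq))
                            * np.sqrt(2.0 / (in_ch * arch.kernel_freq))).astype(self.dtype),
                           requires_grad=True)
                b = Tensor(np.zeros(out_ch, dtype=self.dtype), requires_grad=True)
                self.conv_params.append((w, b))
                length = (length - arch.kernel_freq + 1) // pool
                if length < 1:
                    raise ValueError("frequency axis exhausted; reduce depth/kernel/pool")
                in_ch = out_ch
            self.feature_shape = (n_elec, arch.conv_channels[-1], length)  # (E, C, F')
        else:
            in_ch, H, W = input_shape
            k = arch.kernel_freq
            for out_ch, pool in zip(arch.conv_channels, arch.pools):
                w = Tensor((rng.standard_normal((out_ch, in_ch, k, k))
                            * np.sqrt(2.0 / (in_ch * k * k))).astype(self.dtype),
                           requires_grad=True)
                b = Tensor(np.zeros(out_ch, dtype=self.dtype), requires_grad=True)
                self.conv_params.append((w, b))
                H = (H - k + 1) // pool
                W = (W - k + 1) // pool
                if H < 1 or W < 1:
                    raise ValueError("spatial axes exhausted; reduce depth/kernel/pool")
                in_ch = out_ch
            self.feature_shape = (arch.conv_channels[-1], H, W)  # (C, H', W')
        d_flat = int(np.prod(self.feature_shape))
        # dense tail of the feature extractor: most of the extractor's
        # capacity lives here, where the domain-confusion gradient reaches it
        self.embed_layers: list[tuple[Tensor, Tensor]] = []
        d_in = d_flat
        for width in arch.embed:
            w = Tensor((rng.standard_normal((d_in, width)) * np.sqrt(2.0 / d_in))
                       .astype(self.dtype), requires_grad=True)
            bb = Tensor(np.zeros(width, dtype=self.dtype), requires_grad=True)
            self.embed_layers.append((w, bb))
            d_in = width
        self.top_layers = self._make_head(rng, d_in, 2)
        self.sub_layers = self._make_head(rng, d_in, S)

    def _make_head(self, rng, d_in: int, d_out: int) -> list[tuple[Tensor, Tensor]]:
        layers = []
        for width in (*self.arch.head_hidden, d_out):
            w = Tensor((rng.standard_normal((d_in, width)) * np.sqrt(2.0 / d_in))
                       .astype(self.dtype), requires_grad=True)
            b = Tensor(np.zeros(width, dtype=self.dtype), requires_grad=True)
            layers.append((w, b))
            d_in = width
        return layers

    # -- parameter groups --------------------------------------------------
    @property
    def theta_f(self) -> list[Tensor]:
        return [t for wb in self.conv_params for t in wb] + \
            [t for wb in self.embed_layers for t in wb]

    @property
    def theta_t(self) -> list[Tensor]:
        return [t for wb in self.top_layers for t in wb]

    @property
    def theta_s(self) -> list[Tensor]:
        return [t for wb in self.sub_layers for t in wb]

    # -- forward pieces ----------------------------------------------------
    def features(self, x: np.ndarray) -> Tensor:
        """Base CNN feature block.

        tf mode: (N, E, F) -> (N, E, C, F'); topo: (N, k, H, W) -> (N, C, H', W').
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.shape[1:] != self.input_shape:
            raise ValueError(f"expected input shape {self.input_shape}, got {x.shape[1:]}")
        N = x.shape[0]
        if self.arch.mode == "tf":
            E, F = self.input_shape
            h = Tensor(x.reshape(N * E, 1, F))
            for (w, b), pool in zip(self.conv_params, self.arch.pools):
                # pool before ReLU (equivalent for monotone ReLU, cheaper)
                h = ad.relu(ad.maxpool1d(ad.conv1d(h, w, b), pool))
            C, Fp = h.shape[1], h.shape[2]
            return h.reshape(N, E, C, Fp)
        h = Tensor(x)
        for (w, b), pool in zip(self.conv_params, self.arch.pools):
            h = ad.relu(ad.maxpool2d(ad.conv2d(h, w, b), pool))
        return h

    def embed(self, d_flat: Tensor, capture: list | None = None) -> Tensor:
        """Dense tail of the Base CNN applied to the flattened difference block."""
        h = d_flat
        for w, b in self.embed_layers:
            h = ad.relu(h @ w + b)
            if capture is not None:
                capture.append(h)
        return h

    def head_logprobs(self, z: Tensor, which: str,
                      capture: list | None = None) -> Tensor:
        layers = self.top_layers if which == "top" else self.sub_layers
        h = z
        for i, (w, b) in enumerate(layers):
            h = h @ w + b
            if i < len(layers) - 1:
                h = ad.relu(h)
            if capture is not None:
                capture.append(h)
        return ad.log_softmax(h)

    def group_nll_from_block(self, d_block: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-example NLL of the true class given a (possibly ablated) cue block."""
        z = self.embed(Tensor(d_block.reshape(d_block.shape[0], -1)))
        lp = self.head_logprobs(z, "top").data
        return -lp[np.arange(lp.shape[0]), np.asarray(y, np.intp)]

    def pair_graph(self, B: np.ndarray, A: np.ndarray):
        """Shared forward: returns (d cue block, group log-probs, subject log-probs)."""
        fB = self.features(B)
        fA = self.features(A)
        d = fA - fB
        z = self.embed(d.reshape(d.shape[0], int(np.prod(d.shape[1:]))))
        return d, self.head_logprobs(z, "top"), self.head_logprobs(z, "sub")


def build_models(arch: ArchConfig, S: int, seed: int = 0, lam: float = 0.0,
                 input_shape: tuple[int, ...] = (64, 55),
                 dtype=np.float32) -> ModelBundle:
    """Deterministically initialize a model bundle for ``S`` subjects."""
    return ModelBundle(arch=arch, S=S, lam=lam, seed=seed, input_shape=input_shape,
                       dtype=dtype)


def forward_pair(bundle: ModelBundle, B: np.ndarray, A: np.ndarray):
    """Forward a batch of pairs; returns (group probs, subject probs, d) as arrays."""
    B = np.asarray(B, float)
    A = np.asarray(A, float)
    if B.ndim == len(bundle.input_shape):  # single tuple convenience
        B, A = B[None], A[None]
    d, lp_g, lp_s = bundle.pair_graph(B, A)
    return np.exp(lp_g.data), np.exp(lp_s.data), d.data


def kl_from_uniform(logprobs: Tensor, n_classes: int) -> Tensor:
    """KL(U || h) per example from log-probabilities; shape (N,) summed -> scalar."""
    return -np.log(n_classes) - logprobs.mean(axis=-1)


def losses(bundle: ModelBundle, batch, reduction: str = "mean"):
    """J_g, J_s and the domain-confusion objective J_f for one batch.

    ``batch`` is ``(B, A, y_g, y_s)``.  Per-example negative log-likelihoods
    are reduced by mean (default, matching reported magnitudes) or sum.
    Returns the three scalars as autodiff Tensors plus the mean KL term.
    """
    B, A, y_g, y_s = batch
    if len(np.atleast_1d(y_g)) == 0:
        raise ValueError("empty batch")
    _, lp_g, lp_s = bundle.pair_graph(B, A)
    red = (lambda t: t.mean()) if reduction == "mean" else (lambda t: t.sum())
    J_g = red(-ad.pick(lp_g, np.atleast_1d(y_g)))
    J_s = red(-ad.pick(lp_s, np.atleast_1d(y_s)))
    kl = red(kl_from_uniform(lp_s, bundle.S))
    J_f = J_g + bundle.lam * kl
    return J_g, J_s, J_f, kl


def make_split(dataset: PairDataset, strategy: str, seed: int = 0,
               n_folds: int = 10, train_frac: float = 0.8) -> SplitPlan:
    """Build a deterministic cross-validation plan.

    Strategies
    ----------
    ``timepoint_80_20``
        One fold; 80% of tuples train / 20% validate, stratified per subject
        (the network sees every subject during training).
    ``subject_leave2out_10fold``
        Up to ``n_folds`` folds, each holding out one CON and one EXE
        subject; measures generalization to unseen subjects.
    ``shuffle_subject_labels``
        Leave-two-out folds with group labels reassigned at random at the
        subject level (group sizes preserved) -- a selection-bias control.
    ``shuffle_timepoint_labels``
        Timepoint split with labels shuffled per tuple -- a convergence
        control (chance-level accuracy expected).
    """
    rng = np.random.default_rng(seed)
    S, T = dataset.n_subjects, dataset.n_timepoints
    m = dataset.m

    def _timepoint_folds():
        n_train_total = int(np.floor(train_frac * m))
        per = n_train_total // S
        extra = n_train_total - per * S
        train, val = [], []
        for s in range(S):
            perm = rng.permutation(T) + s * T
            k = per + (1 if s < extra else 0)
            train.append(perm[:k])
            val.append(perm[k:])
        return [(np.sort(np.concatenate(train)), np.sort(np.concatenate(val)))]

    def _leave2out_folds(y_subject: np.ndarray):
        con = np.flatnonzero(y_subject == 0)
        exe = np.flatnonzero(y_subject == 1)
        if con.size < 2 or exe.size < 2:
            raise ValueError("leave-two-out needs >= 2 subjects per group")
        k = min(n_folds, con.size, exe.size)
        con_p, exe_p = rng.permutation(con), rng.permutation(exe)
        folds = []
        all_idx = np.arange(m)
        for i in range(k):
            held = {con_p[i], exe_p[i]}
            mask = np.isin(dataset.subject_of(all_idx), list(held))
            folds.append((all_idx[~mask], all_idx[mask]))
        return folds

    if strategy == "timepoint_80_20":
        return SplitPlan(strategy, seed, _timepoint_folds())
    if strategy == "subject_leave2out_10fold":
        return SplitPlan(strategy, seed, _leave2out_folds(dataset.y_group))
    if strategy == "shuffle_subject_labels":
        y = dataset.y_group.copy()
        y_shuf = y[rng.permutation(S)]  # preserves group sizes
        return SplitPlan(strategy, seed, _leave2out_folds(y_shuf),
                         y_group_subject=y_shuf)
    if strategy == "shuffle_timepoint_labels":
        y_tuple = dataset.y_group[dataset.subject_of(np.arange(m))]
        y_tuple = y_tuple[rng.permutation(m)]
        return SplitPlan(strategy, seed, _timepoint_folds(), y_group_tuple=y_tuple)
    raise ValueError(f"unknown split strategy {strategy!r}")


def evaluate(bundle: ModelBundle, dataset: PairDataset, idx: np.ndarray,
             labels: np.ndarray | None = None, batch_size: int = 512):
    """Timepoint-level group accuracy: overall and per group (CON, EXE)."""
    idx = np.asarray(idx, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("cannot evaluate on an empty tuple set")
    correct = np.zeros(idx.size, dtype=bool)
    y_all = np.empty(idx.size, dtype=np.intp)
    for lo in range(0, idx.size, batch_size):
        sl = slice(lo, min(lo + batch_size, idx.size))
        B, A, y_g, _, _ = dataset.batch(idx[sl])
        if labels is not None:
            y_g = labels[sl]
        _, lp_g, _ = bundle.pair_graph(B, A)
        correct[sl] = lp_g.data.argmax(axis=1) == y_g
        y_all[sl] = y_g
    overall = float(correct.mean())
    per_group = tuple(float(correct[y_all == g].mean()) if np.any(y_all == g) else np.nan
                      for g in (0, 1))
    return overall, per_group


def train(bundle: ModelBundle, dataset: PairDataset, split: SplitPlan,
          cfg: TrainConfig | None = None, fold: int = 0):
    """Adversarially train a bundle on one fold of the split plan.

    Per minibatch: the adversary head takes ``cfg.adversary_steps`` updates
    on J_s with the extractor frozen, then the extractor and group head take
    one update on J_f = J_g + lambda * KL(U || h_s).  Fully reproducible
    given the bundle seed and split.  Raises ``RuntimeError`` on divergence.
    """
    cfg = cfg or TrainConfig()
    train_idx, val_idx = split.folds[fold]
    rng = np.random.default_rng(bundle.seed + 7919 * (fold + 1))
    opt_adv = ad.Adam(bundle.theta_s, lr=cfg.lr)
    opt_main = ad.Adam(bundle.theta_f + bundle.theta_t, lr=cfg.lr)
    history = TrainHistory()

    val_eval = val_idx if val_idx.size <= cfg.val_eval_cap else \
        val_idx[np.linspace(0, val_idx.size - 1, cfg.val_eval_cap).astype(np.intp)]

    def val_group_nll() -> float:
        tot = 0.0
        for lo in range(0, val_eval.size, 1024):
            sl = val_eval[lo:lo + 1024]
            B, A, _, _, _ = dataset.batch(sl)
            y = split.labels_for(dataset, sl)
            _, lp_g, _ = bundle.pair_graph(B, A)
            tot += float(-lp_g.data[np.arange(sl.size), y].sum())
        return tot / val_eval.size

    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        ep_g, ep_s, ep_kl, nb = 0.0, 0.0, 0.0, 0
        for lo in range(0, order.size, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            B, A, _, y_s, _ = dataset.batch(idx)
            y_g = split.labels_for(dataset, idx)
            # One feature forward per batch: the adversary update does not
            # differentiate through the (frozen) extractor, so it can reuse
            # the detached feature difference.
            fB = bundle.features(B)
            fA = bundle.features(A)
            d = fA - fB
            z = bundle.embed(d.reshape(d.shape[0], int(np.prod(d.shape[1:]))))
            for _ in range(cfg.adversary_steps):
                lp_s = bundle.head_logprobs(Tensor(z.data), "sub")
                J_s = (-ad.pick(lp_s, y_s)).mean()
                if not np.isfinite(J_s.data):
                    raise RuntimeError(f"adversary loss diverged at epoch {epoch}")
                opt_adv.zero_grad()
                J_s.backward()
                opt_adv.step()
            lp_g = bundle.head_logprobs(z, "top")
            lp_s2 = bundle.head_logprobs(z, "sub")
            J_g = (-ad.pick(lp_g, y_g)).mean()
            kl = kl_from_uniform(lp_s2, bundle.S).mean()
            J_f = J_g + bundle.lam * kl
            if not np.isfinite(J_f.data):
                raise RuntimeError(f"training loss diverged at epoch {epoch}: "
                                   f"J_g={J_g.data}, KL={kl.data}")
            opt_adv.zero_grad()
            opt_main.zero_grad()
            J_f.backward()
            opt_main.step()
            ep_g += float(J_g.data)
            ep_s += float(J_s.data)
            ep_kl += float(kl.data)
            nb += 1
        acc, acc_pg = evaluate(bundle, dataset, val_eval,
                               labels=split.labels_for(dataset, val_eval))
        history.J_g.append(ep_g / nb)
        history.J_s.append(ep_s / nb)
        history.kl.append(ep_kl / nb)
        history.val_acc.append(acc)
        history.val_acc_group.append(acc_pg)
        if cfg.keep_best:
            vg = val_group_nll()
            if vg < best[0]:
                best = (vg, [p.data.copy() for p in
                             bundle.theta_f + bundle.theta_t + bundle.theta_s])
        logger.info("epoch %d: J_g=%.4f J_s=%.4f KL=%.5f val=%.3f",
                    epoch, ep_g / nb, ep_s / nb, ep_kl / nb, acc)
    if cfg.keep_best and best[1] is not None:
        # history keeps the full trajectory; the returned bundle is the
        # checkpoint with the lowest validation group loss
        for p, data in zip(bundle.theta_f + bundle.theta_t + bundle.theta_s, best[1]):
            p.data = data
    bundle.trained = True
    return bundle, history


def select_lambda(grid, dataset: PairDataset, split: SplitPlan, arch: ArchConfig,
                  cfg: TrainConfig | None = None, seed: int = 0,
                  acc_floor: float = 0.8, S_prime: int | None = None, fold: int = 0):
    """Train one model per lambda and pick the adversary weight.

    lambda* is the candidate that keeps group validation accuracy at or
    above ``acc_floor`` while the validation subject loss J_s sits nearest
    its confusion equilibrium -ln(1/S'); ties favor the larger lambda.
    Returns ``(lambda_star_or_None, rows)`` where each row records lambda,
    final losses, KL and accuracies.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    S_ref = S_prime if S_prime is not None else dataset.n_subjects
    target = np.log(S_ref)
    rows = []
    for lam in grid:
        bundle = build_models(arch, dataset.n_subjects, seed=seed, lam=lam,
                              input_shape=dataset.baseline.shape[1:3])
        bundle, hist = train(bundle, dataset, split, cfg, fold=fold)
        tr_idx, val_idx = split.folds[fold]
        val_eval = val_idx[:4000]
        B, A, y_g, y_s, _ = dataset.batch(val_eval)
        J_g, J_s, _, kl = losses(bundle, (B, A, split.labels_for(dataset, val_eval), y_s))
        acc, acc_pg = evaluate(bundle, dataset, val_eval)
        rows.append({"lam": lam, "J_g": float(J_g.data), "J_s": float(J_s.data),
                     "kl": float(kl.data), "val_acc": acc, "val_acc_group": acc_pg,
                     "bundle": bundle, "history": hist})
    feasible = [r for r in rows if r["val_acc"] >= acc_floor]
    if not feasible:
        warnings.warn(f"no lambda reaches the accuracy floor {acc_floor}",
                      RuntimeWarning, stacklevel=2)
        return None, rows
    best = sorted(feasible, key=lambda r: (abs(r["J_s"] - target), -r["lam"]))[0]
    return best["lam"], rows


def extract_features(bundle: ModelBundle, dataset: PairDataset, layer_tag: str,
                     batch_size: int = 512) -> np.ndarray:
    """Per-subject time-averaged activations of a named layer.

    ``layer_tag`` is ``"feature"`` (the flattened difference feature block)
    or ``"top.k"`` / ``"sub.k"`` for the k-th layer output of a head
    (0-based; the final layer is the pre-softmax logits).  Returns an array
    (n_subjects, dim), tuples averaged over timepoints.
    """
    m = dataset.m
    sums = None
    for lo in range(0, m, batch_size):
        idx = np.arange(lo, min(lo + batch_size, m))
        B, A, _, y_s, _ = dataset.batch(idx)
        d, _, _ = bundle.pair_graph(B, A)
        d_flat = d.data.reshape(d.data.shape[0], -1)
        z = bundle.embed(Tensor(d_flat))
        if layer_tag == "feature":
            out = z.data
        else:
            head, _, k = layer_tag.partition(".")
            if head not in ("top", "sub") or not k.isdigit():
                raise ValueError(f"unknown layer tag {layer_tag!r}")
            capture: list[Tensor] = []
            bundle.head_logprobs(z, head, capture=capture)
            if int(k) >= len(capture):
                raise ValueError(f"layer index {k} out of range for head {head!r}")
            out = capture[int(k)].data
        if sums is None:
            sums = np.zeros((dataset.n_subjects, out.shape[1]))
        np.add.at(sums, y_s, out)
    return sums / dataset.n_timepoints


def feature_behavior_correlation(features: np.ndarray, scores: np.ndarray,
                                 component: int) -> float:
    """Pearson r between one feature component and the behavioral scores."""
    from scipy.stats import pearsonr

    x = np.asarray(features, float)[:, component]
    y = np.asarray(scores, float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(pearsonr(x, y).statistic)
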