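"""Cue-combination Class Activation Maps (ccCAM) with bootstrap-ratio maps.

The channels of the final convolutional feature block (computed on the
session difference ``d = f(A) - f(B)``) are treated as independent
Gaussian cues to the classifier.  Removing cue ``i`` (zeroing its channel)
raises the negative log-likelihood of the correct class from ``eps`` to
``eps_i``; under the Gaussian cue model the increase identifies the cue's
precision,

    1 / sigma_i^2  =  sum_j  2 (eps_i - eps)^(j)  /  ms(mu_i)^(j),

where ``ms`` is the mean-squared value of the cue's map on example ``j``
(the matrix-valued analogue of ``mu_i^2``).  The combined map

    c* = sum_i w_i mu_i,     w_i = (1/sigma_i^2) / sum_k (1/sigma_k^2)

is the class activation map.  Because weights are ratios of precisions,
the construction is insensitive to per-cue feature scale.

The CAM is mapped back to input resolution along the convolved axis
(linear interpolation at receptive-field centers; the electrode axis is
never convolved in tf mode and is left untouched), averaged over
electrodes into a per-frequency importance vector, and summarized per
subject by the bootstrap ratio BSR = mean over time / sd over time --
a reliability score that is large only where the attribution is
consistently signed across the whole task window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .model import ModelBundle
from .tfmaps import PairDataset

logger = logging.getLogger(__name__)

__all__ = ["CueSet", "CAMMap", "BSRMap", "cue_blocks", "ablation_nll",
           "estimate_precisions", "combine_cues", "cam_at_input_resolution",
           "frequency_importance", "bsr", "group_bsr_curves",
           "frequency_bsr_pipeline"]

_EPS = 1e-12


@dataclass
class CueSet:
    """Per-example cue maps with dataset-level precisions and weights."""

    mu: np.ndarray            # (N, C, ...map shape); cue axis first after batch
    y: np.ndarray             # (N,) true class labels
    eps_full: np.ndarray      # (N,) NLL of the full model
    eps_removed: np.ndarray   # (N, C) NLL with cue i zeroed
    precisions: np.ndarray    # (C,) 1/sigma_i^2, >= 0
    weights: np.ndarray       # (C,) normalized; sums to 1
    mode: str = "tf"

    def __post_init__(self):
        if self.weights.size != self.precisions.size or self.weights.size != self.mu.shape[1]:
            raise ValueError("precision/weight vector length must equal cue count")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")


@dataclass
class CAMMap:
    """Class activation maps at input resolution."""

    values: np.ndarray  # (N, E, F) in tf mode; (N, H, W) in topo mode
    mode: str
    subjects: np.ndarray | None = None   # (N,) subject index per map
    timepoints: np.ndarray | None = None


@dataclass
class BSRMap:
    """Per-subject bootstrap ratios plus group summary curves."""

    per_subject: np.ndarray        # (S, F) or (S, H, W)
    group_mean: dict[str, np.ndarray]
    group_se: dict[str, np.ndarray]


def _cue_axis_first(d: np.ndarray, mode: str) -> np.ndarray:
    # tf feature block is (N, E, C, F'); topo is (N, C, H', W')
    return np.moveaxis(d, 2, 1) if mode == "tf" else d


def _cue_axis_back(mu: np.ndarray, mode: str) -> np.ndarray:
    return np.moveaxis(mu, 1, 2) if mode == "tf" else mu


def cue_blocks(bundle: ModelBundle, dataset: PairDataset, idx: np.ndarray,
               batch_size: int = 512):
    """Difference feature blocks arranged (N, C, ...), with labels/subjects/timepoints."""
    idx = np.asarray(idx, dtype=np.intp)
    out, ys, ysub, ts = [], [], [], []
    for lo in range(0, idx.size, batch_size):
        sl = idx[lo:lo + batch_size]
        B, A, y_g, y_s, t = dataset.batch(sl)
        d, _, _ = bundle.pair_graph(B, A)
        out.append(_cue_axis_first(d.data, bundle.arch.mode))
        ys.append(y_g)
        ysub.append(y_s)
        ts.append(t)
    return (np.concatenate(out), np.concatenate(ys), np.concatenate(ysub),
            np.concatenate(ts))


def ablation_nll(bundle: ModelBundle, mu: np.ndarray, y: np.ndarray,
                 cue_index: int | None = None, batch_size: int = 2048) -> np.ndarray:
    """Per-example NLL of the *correct* class, with cue ``cue_index`` zeroed.

    ``mu`` is the cue-first feature block (N, C, ...).  ``cue_index=None``
    gives the full-model NLL.  The group head is evaluated directly on the
    (ablated) feature block; log-probabilities come from a log-sum-exp
    softmax, so zero predicted probability cannot occur.
    """
    if not bundle.trained:
        raise ValueError("ablation requires a trained bundle")
    C = mu.shape[1]
    if cue_index is not None and not (0 <= cue_index < C):
        raise ValueError(f"cue index {cue_index} out of range (C={C})")
    work = mu if cue_index is None else mu.copy()
    if cue_index is not None:
        work[:, cue_index] = 0.0
    work = _cue_axis_back(work, bundle.arch.mode)
    N = work.shape[0]
    nll = np.empty(N)
    y = np.asarray(y, dtype=np.intp)
    for lo in range(0, N, batch_size):
        sl = slice(lo, min(lo + batch_size, N))
        nll[sl] = bundle.group_nll_from_block(work[sl], y[sl])
    return nll


def estimate_precisions(bundle: ModelBundle, dataset: PairDataset,
                        idx: np.ndarray, clamp: bool = True) -> CueSet:
    """Estimate per-cue precisions 1/sigma_i^2 by NLL ablation over the dataset.

    Per-example contributions with near-zero cue mean-square are skipped;
    negative contributions (ablation improving the loss) are clamped to 0
    by default, preserving the nonnegative-precision contract
    (``clamp=False`` keeps them for diagnostics).  A cue whose every
    contribution is skipped gets precision 0 with a warning.
    """
    mu, y, _, _ = cue_blocks(bundle, dataset, idx)
    return estimate_precisions_from_blocks(bundle, mu, y, clamp=clamp)


def estimate_precisions_from_blocks(bundle: ModelBundle, mu: np.ndarray,
                                    y: np.ndarray, clamp: bool = True) -> CueSet:
    N, C = mu.shape[:2]
    eps_full = ablation_nll(bundle, mu, y, None)
    eps_removed = np.stack([ablation_nll(bundle, mu, y, i) for i in range(C)], axis=1)
    ms = (mu.reshape(N, C, -1) ** 2).mean(axis=2)  # (N, C)
    contrib = 2.0 * (eps_removed - eps_full[:, None])
    if clamp:
        contrib = np.maximum(contrib, 0.0)
    valid = ms > _EPS
    prec = np.zeros(C)
    for i in range(C):
        if not np.any(valid[:, i]):
            warnings.warn(f"cue {i}: all contributions skipped; precision set to 0",
                          RuntimeWarning, stacklevel=2)
            continue
        prec[i] = np.sum(contrib[valid[:, i], i] / ms[valid[:, i], i])
    prec = np.maximum(prec, 0.0)
    total = prec.sum()
    if total <= 0:
        warnings.warn("all cue precisions are zero; falling back to uniform weights",
                      RuntimeWarning, stacklevel=2)
        weights = np.full(C, 1.0 / C)
    else:
        weights = prec / total
    return CueSet(mu=mu, y=np.asarray(y, np.intp), eps_full=eps_full,
                  eps_removed=eps_removed, precisions=prec, weights=weights,
                  mode=bundle.arch.mode)


def combine_cues(cueset: CueSet) -> np.ndarray:
    """Precision-weighted combination c* = sum_i w_i mu_i, per example."""
    w = cueset.weights.reshape((1, -1) + (1,) * (cueset.mu.ndim - 2))
    return (w * cueset.mu).sum(axis=1)


def _receptive_centers(bundle: ModelBundle) -> np.ndarray:
    """Input-bin coordinates of each output bin along the convolved axis."""
    centers = np.arange(bundle.input_shape[-1], dtype=float)
    k = bundle.arch.kernel_freq
    for p in bundle.arch.pools:
        L = centers.size - k + 1
        centers = np.array([centers[i:i + k].mean() for i in range(L)])
        q = centers.size // p
        centers = centers[:q * p].reshape(q, p).mean(axis=1)
    return centers


def _interp_matrix(centers: np.ndarray, n_out: int) -> np.ndarray:
    """Linear-interpolation matrix W (n_out x len(centers)), edge-clamped."""
    W = np.zeros((n_out, centers.size))
    for x in range(n_out):
        if x <= centers[0]:
            W[x, 0] = 1.0
        elif x >= centers[-1]:
            W[x, -1] = 1.0
        else:
            j = np.searchsorted(centers, x) - 1
            t = (x - centers[j]) / (centers[j + 1] - centers[j])
            W[x, j], W[x, j + 1] = 1 - t, t
    return W


def cam_at_input_resolution(bundle: ModelBundle, cstar: np.ndarray,
                            subjects: np.ndarray | None = None,
                            timepoints: np.ndarray | None = None) -> CAMMap:
    """Upsample combined maps to input resolution.

    tf mode: the electrode axis is untouched (it is never convolved); the
    frequency axis is linearly interpolated back to the input grid at the
    receptive-field centers of the final feature bins.  topo mode applies
    the same interpolation to both spatial axes.
    """
    centers = _receptive_centers(bundle)
    if bundle.arch.mode == "tf":
        E, F = bundle.input_shape
        if cstar.shape[1] != E or cstar.shape[2] != centers.size:
            raise ValueError("combined map geometry does not match the bundle")
        W = _interp_matrix(centers, F)
        values = cstar @ W.T
    else:
        k, H, Wd = bundle.input_shape
        M = _interp_matrix(centers, H)  # square inputs: same grid both axes
        values = np.einsum("hy,nyx,wx->nhw", M, cstar, M)
    return CAMMap(values=values, mode=bundle.arch.mode, subjects=subjects,
                  timepoints=timepoints)


def frequency_importance(cam: CAMMap) -> np.ndarray:
    """Average the CAM over electrodes: per-frequency importance, (N, F)."""
    if cam.mode != "tf":
        raise ValueError("frequency importance is defined for tf-mode CAMs only")
    return cam.values.mean(axis=1)


def bsr(importance: np.ndarray, subjects: np.ndarray, n_subjects: int) -> np.ndarray:
    """Per-subject bootstrap ratio over timepoints: mean_t / sd_t, per bin.

    ``importance`` is (N, ...) with one row per timepoint sample and
    ``subjects`` maps each row to its subject.  Requires >= 2 timepoints
    per subject; a time-constant series hits an epsilon guard (logged).
    """
    importance = np.asarray(importance, float)
    subjects = np.asarray(subjects, np.intp)
    out = np.empty((n_subjects,) + importance.shape[1:])
    for s in range(n_subjects):
        rows = importance[subjects == s]
        if rows.shape[0] < 2:
            raise ValueError(f"subject {s}: BSR needs >= 2 timepoints")
        sd = rows.std(axis=0, ddof=1)
        n_guard = int(np.sum(sd <= _EPS))
        if n_guard:
            logger.warning("bsr: %d time-constant bins for subject %d (epsilon guard)",
                           n_guard, s)
            warnings.warn("time-constant attribution series; epsilon guard applied",
                          RuntimeWarning, stacklevel=2)
        out[s] = rows.mean(axis=0) / np.maximum(sd, _EPS)
    return out


def group_bsr_curves(per_subject: np.ndarray, y_group: np.ndarray) -> BSRMap:
    """Group-mean BSR with standard error over subjects, per group."""
    names = ("CON", "EXE")
    mean, se = {}, {}
    for g, name in enumerate(names):
        rows = per_subject[np.asarray(y_group) == g]
        mean[name] = rows.mean(axis=0)
        se[name] = rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0])
    return BSRMap(per_subject=per_subject, group_mean=mean, group_se=se)


def frequency_bsr_pipeline(bundle: ModelBundle, dataset: PairDataset,
                           idx: np.ndarray | None = None):
    """Full attribution chain: cues -> precisions -> CAM -> importance -> BSR.

    Returns ``(bsr_map, cueset)`` where ``bsr_map.per_subject`` is
    (n_subjects, n_freqs).
    """
    if idx is None:
        idx = np.arange(dataset.m)
    mu, y, y_s, t = cue_blocks(bundle, dataset, idx)
    cueset = estimate_precisions_from_blocks(bundle, mu, y)
    cstar = combine_cues(cueset)
    cam = cam_at_input_resolution(bundle, cstar, subjects=y_s, timepoints=t)
    imp = frequency_importance(cam)
    per_subject = bsr(imp, y_s, dataset.n_subjects)
    return group_bsr_curves(per_subject, dataset.y_group), cueset
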