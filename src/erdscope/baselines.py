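"""Comparator classifiers: random forests, SVM, and CSP features.

These benchmark the adversarial CNN's subject-level generalization under
byte-identical fold plans.  Random forests and SVMs consume the same
per-timepoint (B, A) tuples as the CNN, flattened either as the session
difference A - B (default) or as a concatenation.  Variants:

* ``rf_raw`` -- random forest on the raw flattened features;
* ``rf_freqweighted`` -- each frequency bin multiplied by its frequency in
  Hz before flattening (flattens the 1/f spectral envelope);
* ``rf_bandbinned`` -- mean power per canonical EEG band per electrode
  (delta 1-4, theta 4-8, alpha 8-12, beta 15-29, gamma 30-55 Hz);
* ``svm`` -- RBF support-vector machine on standardized raw features;
* ``csp`` -- common spatial patterns computed from raw epochs' spatial
  covariances (filters fit on training subjects only), log-variance
  features averaged per session, post-minus-baseline differences
  classified per subject with a random forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SplitPlan
from .tfmaps import PairDataset

__all__ = ["BaselineSpec", "BaselineResult", "freq_weight", "band_bin",
           "run_baseline", "CANONICAL_BANDS"]

_METHODS = ("rf_raw", "rf_freqweighted", "rf_bandbinned", "svm", "csp")

#: Canonical EEG bands as (name, lo, hi); membership lo <= f < hi, so beta
#: spans bins 15-29 Hz and gamma 30-55 Hz on the 1-55 Hz grid.  The 12-15 Hz
#: gap between alpha and beta follows the usual motor-EEG convention.
CANONICAL_BANDS = (("delta", 1.0, 4.0), ("theta", 4.0, 8.0), ("alpha", 8.0, 12.0),
                   ("beta", 15.0, 30.0), ("gamma", 30.0, 56.0))


@dataclass(frozen=True)
class BaselineSpec:
    method: str
    pair_mode: str = "difference"  # or "concat"
    n_estimators: int = 100
    csp_components: int = 6
    seed: int = 0
    bands: tuple = CANONICAL_BANDS

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.pair_mode not in ("difference", "concat"):
            raise ValueError("pair_mode must be 'difference' or 'concat'")
        for i, (_, lo, hi) in enumerate(self.bands):
            if hi <= lo:
                raise ValueError("band upper edge must exceed lower edge")
            for _, lo2, hi2 in self.bands[i + 1:]:
                if lo < hi2 and lo2 < hi:
                    raise ValueError("bands must not overlap")


@dataclass
class BaselineResult:
    spec: BaselineSpec
    fold_acc: list[float]
    fold_acc_group: list[tuple[float, float]]
    mean: float = field(init=False)
    se: float = field(init=False)

    def __post_init__(self):
        acc = np.asarray(self.fold_acc)
        self.mean = float(acc.mean())
        self.se = float(acc.std(ddof=1) / np.sqrt(acc.size)) if acc.size > 1 else 0.0


def freq_weight(features: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Multiply power in each frequency bin by the bin's frequency in Hz.

    ``features`` is (..., electrodes, freqs); the exact 1/f spectrum maps
    to a constant.
    """
    return features * np.asarray(freqs, float)


def band_bin(features: np.ndarray, freqs: np.ndarray,
             bands=CANONICAL_BANDS) -> np.ndarray:
    """Mean power per canonical band: (..., electrodes, freqs) -> (..., electrodes, n_bands)."""
    freqs = np.asarray(freqs, float)
    cols = []
    for _, lo, hi in bands:
        sel = (freqs >= lo) & (freqs < hi)
        if not np.any(sel):
            raise ValueError(f"band ({lo}, {hi}) contains no frequency bins")
        cols.append(features[..., sel].mean(axis=-1))
    return np.stack(cols, axis=-1)


def _tuple_features(spec: BaselineSpec, dataset: PairDataset, idx: np.ndarray):
    B, A, y_g, y_s, _ = dataset.batch(idx)
    if spec.method == "rf_freqweighted":
        B, A = (freq_weight(x, dataset.freqs) for x in (B, A))
    elif spec.method == "rf_bandbinned":
        B, A = (band_bin(x, dataset.freqs, spec.bands) for x in (B, A))
    n = B.shape[0]
    if spec.pair_mode == "difference":
        X = (A - B).reshape(n, -1)
    else:
        X = np.concatenate([B.reshape(n, -1), A.reshape(n, -1)], axis=1)
    return X, y_g


def _make_classifier(spec: BaselineSpec):
    if spec.method == "svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        return make_pipeline(StandardScaler(), SVC(kernel="rbf"))
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(n_estimators=spec.n_estimators,
                                  random_state=spec.seed, n_jobs=1)


def _accuracy(pred: np.ndarray, y: np.ndarray):
    overall = float((pred == y).mean())
    pg = tuple(float((pred[y == g] == g).mean()) if np.any(y == g) else np.nan
               for g in (0, 1))
    return overall, pg


def run_baseline(spec: BaselineSpec, dataset: PairDataset, split: SplitPlan,
                 epochs_by_subject: dict | None = None) -> BaselineResult:
    """Evaluate a comparator under the CNN's fold plan.

    RF/SVM methods classify per-timepoint tuples; the CSP method requires
    ``epochs_by_subject`` mapping subject id -> (baseline EpochSet, post
    EpochSet) and classifies at the subject level (one covariance-derived
    feature vector per subject).
    """
    if spec.method == "csp":
        if epochs_by_subject is None:
            raise ValueError("CSP baseline requires raw epochs")
        return _run_csp(spec, dataset, split, epochs_by_subject)
    fold_acc, fold_pg = [], []
    for train_idx, val_idx in split.folds:
        Xtr, ytr = _tuple_features(spec, dataset, train_idx)
        ytr = split.labels_for(dataset, train_idx)
        Xva, _ = _tuple_features(spec, dataset, val_idx)
        yva = split.labels_for(dataset, val_idx)
        clf = _make_classifier(spec)
        clf.fit(Xtr, ytr)
        acc, pg = _accuracy(clf.predict(Xva), yva)
        fold_acc.append(acc)
        fold_pg.append(pg)
    return BaselineResult(spec=spec, fold_acc=fold_acc, fold_acc_group=fold_pg)


def _run_csp(spec: BaselineSpec, dataset: PairDataset, split: SplitPlan,
             epochs_by_subject: dict) -> BaselineResult:
    import warnings as _w

    from mne.decoding import CSP

    sids = dataset.subject_ids
    fold_acc, fold_pg = [], []
    for train_idx, val_idx in split.folds:
        tr_sub = np.unique(dataset.subject_of(train_idx))
        va_sub = np.unique(dataset.subject_of(val_idx))
        X_ep, y_ep = [], []
        for s in tr_sub:
            for sess in epochs_by_subject[sids[s]]:
                X_ep.append(np.asarray(sess.data))
                y_ep.append(np.full(sess.data.shape[0], dataset.y_group[s]))
        X_ep = np.concatenate(X_ep)
        y_ep = np.concatenate(y_ep)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            csp = CSP(n_components=spec.csp_components, log=True)
            csp.fit(X_ep, y_ep)

            def subject_vec(s):
                base, post = epochs_by_subject[sids[s]]
                fb = csp.transform(np.asarray(base.data)).mean(axis=0)
                fp = csp.transform(np.asarray(post.data)).mean(axis=0)
                return fp - fb

            Xtr = np.stack([subject_vec(s) for s in tr_sub])
            Xva = np.stack([subject_vec(s) for s in va_sub])
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(n_estimators=spec.n_estimators,
                                     random_state=spec.seed, n_jobs=1)
        clf.fit(Xtr, dataset.y_group[tr_sub])
        acc, pg = _accuracy(clf.predict(Xva), dataset.y_group[va_sub])
        fold_acc.append(acc)
        fold_pg.append(pg)
    return BaselineResult(spec=spec, fold_acc=fold_acc, fold_acc_group=fold_pg)
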