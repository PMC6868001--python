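"""Point-wise group statistics with sliding-window Simes correction.

Group BSR maps are compared bin by bin (or pixel by pixel) with a one-way
ANOVA across subjects.  Because neighbouring bins are strongly correlated
(the network's receptive fields overlap), the raw p-values are corrected
with the Simes procedure applied in a sliding window centered on each bin:
with ordered window p-values p_(1) <= ... <= p_(L),

    p'_j = min_i  L * p_(i) / i,

clipped at 1.  Window length 5 is used for frequency curves and a 3 x 3
window for topographic images (matching the convolutional kernel sizes);
at array edges the window shrinks symmetrically and L is replaced by the
actual window size.  Bins with corrected p below alpha = 0.05 are reported
as maximal contiguous intervals (1D) or connected components (2D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PMap", "anova_pointwise", "simes_window", "simes_1d", "simes_2d",
           "significant_regions"]


@dataclass
class PMap:
    """Raw and Simes-corrected p-values on a 1D or 2D grid."""

    p: np.ndarray
    p_corr: np.ndarray
    L: int | tuple[int, int]
    alpha: float = 0.05

    def __post_init__(self):
        if self.p.shape != self.p_corr.shape:
            raise ValueError("raw and corrected p-value shapes must match")
        for arr in (self.p, self.p_corr):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("p-values must lie in [0, 1]")


def anova_pointwise(group1: np.ndarray, group2: np.ndarray) -> np.ndarray:
    """One-way ANOVA p-value per bin between two groups of subject-level values.

    ``group1``/``group2`` are (subjects, bins...) arrays.  With two groups
    this is equivalent to the two-sample t-test (F = t^2).  A bin with zero
    within-group variance gets the limit p-value (0 if the means differ,
    1 if they coincide) with a warning.
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group at every bin")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(g1, g2, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        warnings.warn("zero within-group variance at some bins; limit p-values used",
                      RuntimeWarning, stacklevel=2)
        same = np.isclose(g1.mean(axis=0), g2.mean(axis=0))
        p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    return p


def simes_window(window: np.ndarray) -> float:
    """Simes-corrected p-value of the center of one window (clipped at 1).

    The factor is computed as ``p * (L/i)`` so the i = L term is exactly
    the identity: a constant window maps to itself bit-for-bit.
    """
    ps = np.sort(np.asarray(window, float).ravel())
    L = ps.size
    return float(min(1.0, np.min(ps * (L / np.arange(1, L + 1)))))


def simes_1d(p: np.ndarray, L: int = 5) -> np.ndarray:
    """Sliding-window Simes correction of a p-value vector.

    ``L`` must be odd (centered window).  At the edges the window shrinks
    symmetrically: the half-width becomes ``min(w, j, n-1-j)`` and the
    Simes factor uses the actual window length.
    """
    p = np.asarray(p, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("simes_1d expects a non-empty 1D vector")
    if L < 1 or L % 2 == 0:
        raise ValueError("window length must be odd and >= 1")
    w = L // 2
    n = p.size
    out = np.empty(n)
    for j in range(n):
        h = min(w, j, n - 1 - j)
        out[j] = simes_window(p[j - h:j + h + 1])
    return out


def simes_2d(p: np.ndarray, window: tuple[int, int] = (3, 3)) -> np.ndarray:
    """Sliding-window Simes correction of a p-value image (default 3 x 3)."""
    p = np.asarray(p, float)
    if p.ndim != 2:
        raise ValueError("simes_2d expects a 2D image")
    wy, wx = window
    if wy % 2 == 0 or wx % 2 == 0 or wy < 1 or wx < 1:
        raise ValueError("window dims must be odd and >= 1")
    if wy > p.shape[0] or wx > p.shape[1]:
        raise ValueError("window larger than the image")
    hy, hx = wy // 2, wx // 2
    H, W = p.shape
    out = np.empty_like(p)
    for i in range(H):
        ey = min(hy, i, H - 1 - i)
        for j in range(W):
            ex = min(hx, j, W - 1 - j)
            out[i, j] = simes_window(p[i - ey:i + ey + 1, j - ex:j + ex + 1])
    return out


def significant_regions(pmap: PMap):
    """Mask of significant bins plus contiguous intervals / components.

    1D: returns ``(mask, intervals)`` with intervals as (start, stop)
    index pairs, stop inclusive.  2D: ``(mask, labels, n_components)``
    using 4-connectivity.
    """
    mask = pmap.p_corr < pmap.alpha
    if pmap.p_corr.ndim == 1:
        intervals = []
        in_run = False
        for i, flag in enumerate(mask):
            if flag and not in_run:
                start, in_run = i, True
            elif not flag and in_run:
                intervals.append((start, i - 1))
                in_run = False
        if in_run:
            intervals.append((start, mask.size - 1))
        return mask, intervals
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=np.array([[0, 1, 0],
                                                        [1, 1, 1],
                                                        [0, 1, 0]]))
    return mask, labels, n
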