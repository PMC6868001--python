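"""Topographic scalp maps: 2D projection, interpolation, frame stacking.

Band-limited normalized power is projected from the 3D electrode
positions onto a 2D disk (azimuthal equidistant projection: the angular
distance from the vertex becomes the radius, azimuth is preserved), then
rasterized to a 64 x 64 image by piecewise-cubic scattered interpolation
(Clough-Tocher on a Delaunay triangulation, which reproduces the electrode
values exactly at their own locations).  Three consecutive frames are
stacked into a 3 x 64 x 64 tensor; non-overlapping windows tile the task
period, so 7500 timepoints yield 2500 tensors per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .montage import ElectrodeLayout
from .tfmaps import TFSeries

__all__ = ["TopoTensor", "project_2d", "band_series", "render_topo_frame",
           "stack_frames"]


@dataclass
class TopoTensor:
    """A stack of ``k`` consecutive scalp frames for one subject-session."""

    frames: np.ndarray  # (k, grid, grid)
    window_index: int
    subject_id: str = ""
    session_tag: str = ""
    band: tuple[float, float] = (23.0, 33.0)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (k, grid, grid)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")


def project_2d(layout: ElectrodeLayout) -> np.ndarray:
    """Azimuthal equidistant projection of electrode positions to the plane.

    The vertex (straight up, +z) maps to the origin; the radius of each
    projected point is its polar angle scaled so that the equator lands on
    the unit circle, and the azimuth (x right, y front) is preserved.
    """
    pos = layout.pos3d
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms <= 0):
        raise ValueError("degenerate electrode coordinate with zero norm")
    theta = np.arccos(np.clip(pos[:, 2] / norms, -1.0, 1.0))
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    r = theta / (np.pi / 2.0)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def band_series(tf: TFSeries, band: tuple[float, float]) -> np.ndarray:
    """Mean normalized power over the inclusive frequency band, per electrode
    and timepoint: (electrodes, timepoints)."""
    lo, hi = band
    sel = (tf.freqs >= lo) & (tf.freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"band {band} contains no frequency bins")
    return tf.values[:, sel, :].mean(axis=1)


def render_topo_frame(values: np.ndarray, coords2d: np.ndarray,
                      grid: int = 64, fill: float = 0.0) -> np.ndarray:
    """Rasterize per-electrode scalars to a ``grid x grid`` scalp image.

    Scattered cubic (Clough-Tocher) interpolation inside the electrode
    convex hull; pixels outside the hull are set to ``fill``.
    """
    from scipy.interpolate import CloughTocher2DInterpolator

    values = np.asarray(values, dtype=float)
    coords2d = np.asarray(coords2d, dtype=float)
    if values.shape[0] != coords2d.shape[0]:
        raise ValueError("one value per electrode required")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite electrode values")
    lo, hi = coords2d.min(axis=0), coords2d.max(axis=0)
    pad = 0.02 * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid)
    gx, gy = np.meshgrid(xs, ys)
    interp = CloughTocher2DInterpolator(coords2d, values)
    img = interp(gx, gy)
    img[~np.isfinite(img)] = fill
    return img


def stack_frames(frames: np.ndarray, k: int = 3, **meta) -> list[TopoTensor]:
    """Cut a (T, grid, grid) frame sequence into non-overlapping k-frame stacks.

    Tensor ``j`` holds frames ``(jk, ..., jk+k-1)``; up to ``k-1`` leftover
    frames at the end are dropped.  ``T < k`` yields an empty list with a
    warning.
    """
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    if T < k:
        warnings.warn(f"only {T} frames for window size {k}; no tensors produced",
                      RuntimeWarning, stacklevel=2)
        return []
    n = T // k
    return [TopoTensor(frames=frames[j * k:(j + 1) * k], window_index=j, **meta)
            for j in range(n)]
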