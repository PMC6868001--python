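"""Time-frequency maps: Morlet decomposition, baseline normalization, pairing.

The analysis operates on per-session time-frequency (TF) maps: for every
electrode, squared-magnitude Morlet wavelet coefficients on a 1 Hz grid
(1-55 Hz, wave number 7), normalized to the mean spectral power in the
0.5 s window preceding the task cue, averaged over trials, and sliced to
the task window 0.5-3.5 s after the cue.  A session is then an
``electrodes x frequencies x timepoints`` array of dimensionless power
ratios, where event-related desynchronization (ERD) reads directly as
values below 1.

Paired baseline/post sessions from every subject are assembled into a
:class:`PairDataset` of per-timepoint training tuples
``(B_ts, A_ts, y_group, y_subject, t)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FREQS",
    "TFSeries",
    "PairDataset",
    "morlet_power",
    "normalize_to_prestim",
    "session_tf",
    "build_pair_dataset",
]

#: The decomposition grid: 1-55 Hz at 1 Hz resolution (55 bins).
DEFAULT_FREQS = np.arange(1.0, 56.0)

#: Morlet wave number (cycles per wavelet).
DEFAULT_WAVE_NUMBER = 7

_EPS = 1e-12


@dataclass
class TFSeries:
    """Normalized TF power for one subject-session: (electrodes, freqs, time)."""

    values: np.ndarray
    freqs: np.ndarray = field(default_factory=lambda: DEFAULT_FREQS.copy())
    t0: float = 0.5  # task-window start relative to the cue, seconds
    subject_id: str = ""
    session_tag: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("TFSeries values must be (electrodes, freqs, timepoints)")
        if self.values.shape[1] != self.freqs.size:
            raise ValueError("frequency axis length mismatch")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("TFSeries values must be finite and strictly positive")
        df = np.diff(self.freqs)
        if self.freqs.size > 1 and not np.allclose(df, df[0]) or np.any(df <= 0):
            raise ValueError("frequency axis must be strictly increasing with uniform spacing")

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]


class PairDataset:
    """Per-timepoint tuples (B, A, y_g, y_s, t) over all subjects.

    Tuples are indexed flat as ``i = s * T + t`` (subject-major, deterministic
    order); the underlying session arrays are stored once and sliced on
    demand, so the dataset holds ``2 * S * E * F * T`` floats, not ``m``
    copies of the matrices.
    """

    GROUPS = ("CON", "EXE")

    def __init__(self, baseline: np.ndarray, post: np.ndarray, y_group: np.ndarray,
                 subject_ids: list[str], freqs: np.ndarray | None = None):
        baseline = np.asarray(baseline, dtype=float)
        post = np.asarray(post, dtype=float)
        if baseline.shape != post.shape:
            raise ValueError("baseline and post tensors must share shape (S, E, F, T)")
        if baseline.ndim != 4:
            raise ValueError("expected (subjects, electrodes, freqs, timepoints)")
        self.baseline = baseline
        self.post = post
        self.y_group = np.asarray(y_group, dtype=np.intp)
        if self.y_group.shape != (baseline.shape[0],):
            raise ValueError("one group label per subject required")
        self.subject_ids = list(subject_ids)
        self.freqs = DEFAULT_FREQS.copy() if freqs is None else np.asarray(freqs, float)

    @property
    def n_subjects(self) -> int:
        return self.baseline.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.baseline.shape[3]

    @property
    def m(self) -> int:
        """Total tuple count: subjects x timepoints."""
        return self.n_subjects * self.n_timepoints

    def subject_of(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=np.intp) // self.n_timepoints

    def timepoint_of(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=np.intp) % self.n_timepoints

    def batch(self, idx):
        """Materialize tuples at flat indices: (B, A, y_g, y_s, t) arrays."""
        idx = np.asarray(idx, dtype=np.intp)
        s = self.subject_of(idx)
        t = self.timepoint_of(idx)
        B = self.baseline[s, :, :, t]  # (n, E, F)
        A = self.post[s, :, :, t]
        return B, A, self.y_group[s], s, t


def morlet_power(epochs, freqs=None, wave_number: int = DEFAULT_WAVE_NUMBER,
                 chunk: int = 8) -> np.ndarray:
    """Squared-magnitude Morlet coefficients of an epoch set.

    Parameters
    ----------
    epochs
        An epoch container with ``data`` (epochs, electrodes, samples) and
        sampling rate ``fs``.
    freqs
        Frequencies in Hz (default 1-55 at 1 Hz).  All must lie below the
        Nyquist frequency.
    wave_number
        Number of cycles of the Morlet wavelet (center-frequency to
        bandwidth ratio); 7 by default.
    chunk
        Epochs are decomposed in chunks of this size to bound memory.

    Returns
    -------
    power : (epochs, electrodes, freqs, samples) array
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if wave_number < 1:
        raise ValueError("wave_number must be >= 1")
    if freqs.max() >= epochs.fs / 2:
        raise ValueError(
            f"max frequency {freqs.max()} Hz is at/above Nyquist ({epochs.fs / 2} Hz)")
    data = np.asarray(epochs.data, dtype=float)
    n = data.shape[2]
    # Low-frequency wavelets (e.g. 7 cycles at 1 Hz) can exceed the epoch
    # length; compute on a reflect-padded copy and crop, so the retained
    # samples are unaffected by the padding choice at all but edge samples.
    from mne.time_frequency import morlet as _morlet_basis

    longest = max(w.size for w in _morlet_basis(epochs.fs, freqs, n_cycles=wave_number))
    pad = max(0, (longest - n) // 2 + 1)
    if pad:
        data = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    out = np.empty(epochs.data.shape[:2] + (freqs.size, n))
    for lo in range(0, data.shape[0], chunk):
        sl = slice(lo, min(lo + chunk, data.shape[0]))
        p = tfr_array_morlet(
            data[sl], sfreq=epochs.fs, freqs=freqs, n_cycles=wave_number,
            output="power", zero_mean=True, verbose="error")
        out[sl] = p[..., pad:pad + n] if pad else p
    return out


def normalize_to_prestim(power: np.ndarray, onset_index: int, fs: float,
                         pre_window_s: float = 0.5, mode: str = "ratio") -> np.ndarray:
    """Normalize TF power to the mean power in the pre-cue window.

    Each (epoch, electrode, frequency) series is divided by its own mean
    power over the ``pre_window_s`` seconds immediately before the cue
    (``mode='ratio'``, the default); ``'db'`` and ``'percent'`` variants are
    provided for convention compatibility.  A zero pre-stimulus mean is
    guarded with a small epsilon and logged.
    """
    n_pre = int(round(pre_window_s * fs))
    if n_pre < 1 or onset_index - n_pre < 0:
        raise ValueError("pre-stimulus window does not fit inside the epoch")
    base = power[..., onset_index - n_pre:onset_index].mean(axis=-1, keepdims=True)
    if np.any(base <= _EPS):
        warnings.warn("zero/near-zero pre-stimulus mean power; epsilon guard applied",
                      RuntimeWarning, stacklevel=2)
        logger.warning("normalize_to_prestim: %d channels hit the epsilon guard",
                       int(np.sum(base <= _EPS)))
        base = np.maximum(base, _EPS)
    ratio = power / base
    if mode == "ratio":
        return ratio
    if mode == "db":
        return 10.0 * np.log10(np.maximum(ratio, _EPS))
    if mode == "percent":
        return 100.0 * (ratio - 1.0)
    raise ValueError(f"unknown normalization mode {mode!r}")


def session_tf(epochs, freqs=None, wave_number: int = DEFAULT_WAVE_NUMBER,
               task_window: tuple[float, float] = (0.5, 3.5),
               pre_window_s: float = 0.5, mode: str = "ratio",
               per_epoch_normalization: bool = True) -> TFSeries:
    """Trial-averaged normalized TF map for one session, task window only.

    The wavelet transform is computed on the full epoch and sliced to the
    task window afterwards, so wavelet edge effects stay outside the
    retained 0.5-3.5 s segment.  Normalization is applied per epoch before
    averaging by default (``per_epoch_normalization=False`` normalizes the
    trial average instead).
    """
    data = np.asarray(epochs.data)
    if data.shape[0] < 1:
        raise ValueError("session_tf requires at least one epoch")
    power = morlet_power(epochs, freqs=freqs, wave_number=wave_number)
    if per_epoch_normalization:
        power = normalize_to_prestim(power, epochs.onset_index, epochs.fs,
                                     pre_window_s, mode=mode)
        avg = power.mean(axis=0)
    else:
        avg = normalize_to_prestim(power.mean(axis=0), epochs.onset_index,
                                   epochs.fs, pre_window_s, mode=mode)
    lo = epochs.onset_index + int(round(task_window[0] * epochs.fs))
    hi = epochs.onset_index + int(round(task_window[1] * epochs.fs))
    if hi > avg.shape[-1]:
        raise ValueError("task window extends beyond the epoch")
    values = np.maximum(avg[..., lo:hi], _EPS)  # strict positivity contract
    return TFSeries(values=values,
                    freqs=DEFAULT_FREQS.copy() if freqs is None else np.asarray(freqs, float),
                    t0=task_window[0], subject_id=str(epochs.subject_id),
                    session_tag=str(epochs.session_tag))


def build_pair_dataset(baseline: list[TFSeries], post: list[TFSeries],
                       groups: list[str]) -> PairDataset:
    """Assemble paired per-timepoint tuples from matched session TF maps.

    ``baseline[i]`` and ``post[i]`` must belong to the same subject and share
    the electrode/frequency/timepoint geometry; ``groups[i]`` is the
    subject's group label (``"CON"`` or ``"EXE"``).
    """
    if not (len(baseline) == len(post) == len(groups)):
        raise ValueError("baseline, post and groups must have equal length")
    if len(baseline) == 0:
        raise ValueError("empty cohort")
    y = np.array([PairDataset.GROUPS.index(g) for g in groups], dtype=np.intp)
    subject_ids = []
    for b, a in zip(baseline, post):
        if b.subject_id != a.subject_id:
            raise ValueError(f"subject mismatch: {b.subject_id!r} vs {a.subject_id!r}")
        if b.values.shape != a.values.shape:
            raise ValueError(f"session shape mismatch for subject {b.subject_id!r}")
        subject_ids.append(b.subject_id)
    B = np.stack([s.values for s in baseline])
    A = np.stack([s.values for s in post])
    return PairDataset(B, A, y, subject_ids, freqs=baseline[0].freqs.copy())
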