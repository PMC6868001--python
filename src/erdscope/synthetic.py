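"""Synthetic EEG cohorts with a planted, ground-truth-labeled group effect.

The generator emulates the data a paired-session motor-task EEG study
produces after time-frequency preprocessing, at the level the downstream
pipeline consumes:

* 64 electrodes (standard extended 10-20 cap), 55 frequency bins (1-55 Hz),
  normalized power ratios with task-locked ERD dips in the alpha and beta
  ranges over sensorimotor electrodes;
* per-subject spectral *fingerprints* -- smooth random gain curves over
  frequency, identical in a subject's two sessions -- which give a
  subject-adversarial classifier a confound to remove;
* a group-specific post-session ERD attenuation confined to a narrow
  frequency band at selected electrodes (the planted effect the pipeline
  must recover), with per-subject responsiveness jitter;
* lognormal per-timepoint noise whose variance grows toward low
  frequencies, echoing the pink-noise character of raw EEG spectra;
* behavioral retention scores linearly tied to each subject's *realized*
  (not nominal) effect magnitude.

Raw voltage epochs (1/f background plus band-limited oscillators whose
amplitude drops after the cue) are also provided to exercise the wavelet
stage end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tfmaps import DEFAULT_FREQS, TFSeries

__all__ = [
    "GroundTruth",
    "EpochSet",
    "RawEpochConfig",
    "BehaviorTable",
    "TFCohort",
    "default_affected_electrodes",
    "simulate_tf_cohort",
    "simulate_raw_epochs",
    "simulate_behavior",
]

#: Sensorimotor labels of the 64-channel cap carrying the planted effect.
_SENSORIMOTOR = ("C3", "C1", "Cz", "C2", "C4", "FC3", "FC1", "FC2", "FC4",
                 "CP3", "CP1", "CPz", "CP2", "CP4")

#: Log-sd of per-subject responsiveness jitter around the nominal effect.
RESPONSIVENESS_SD = 0.25


def default_affected_electrodes() -> tuple[int, ...]:
    """Indices of the sensorimotor electrode set in the standard 64-cap."""
    from .montage import _CAP64

    return tuple(_CAP64.index(lab) for lab in _SENSORIMOTOR)


@dataclass(frozen=True)
class GroundTruth:
    """Planted-effect parameters; the label against which recovery is judged.

    ``effect_size`` multiplies post-session normalized band power of the
    effect group inside ``[band_lo, band_hi]`` Hz at ``affected_electrodes``
    (values > 1 attenuate ERD, i.e. pull the power ratio back toward 1);
    ``effect_size = 1`` is the null.  ``subject_confound_scale`` is the
    log-amplitude of the per-subject spectral fingerprint (identical in both
    sessions).  ``session_shift_scale`` is the log-amplitude of each
    subject's *session reactivity* -- a smooth random spectral shift of the
    post session relative to baseline, uncorrelated with group, emulating
    session-to-session variability (cap placement, impedance, vigilance).
    This shift is what lets an unregularized classifier memorize subjects
    from the paired difference instead of learning the group effect.
    ``session_shift_coherence`` interpolates between scalp-heterogeneous
    shifts (0: the spectral curve carries an independent signed weight per
    electrode) and scalp-coherent ones (1: a global spectral curve plus a
    broadband per-electrode gain).  Coherent shifts are a low-dimensional,
    blatant subject signature -- the regime in which an unregularized
    classifier shortcuts to subject identity and the adversary pays off
    most clearly.
    """

    band_lo: float = 27.0
    band_hi: float = 29.0
    affected_electrodes: tuple[int, ...] = field(default_factory=default_affected_electrodes)
    effect_size: float = 1.35
    subject_confound_scale: float = 0.30
    session_shift_scale: float = 0.25
    session_shift_coherence: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.band_lo <= self.band_hi <= 55):
            raise ValueError("planted band must satisfy 1 <= lo <= hi <= 55")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if len(self.affected_electrodes) == 0:
            raise ValueError("affected_electrodes must be non-empty")


@dataclass
class EpochSet:
    """Raw voltage epochs for one subject-session."""

    data: np.ndarray  # (epochs, electrodes, samples)
    fs: float
    onset_index: int
    subject_id: str = ""
    session_tag: str = "baseline"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be (epochs, electrodes, samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.data.shape[2]
        if self.onset_index < int(round(0.5 * self.fs)):
            raise ValueError("epoch must provide >= 0.5 s of pre-event context")
        if n - self.onset_index < int(round(3.5 * self.fs)):
            raise ValueError("epoch must provide >= 3.5 s of post-event context")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epochs contain non-finite samples")


@dataclass(frozen=True)
class RawEpochConfig:
    """Configuration for one subject-session of simulated raw epochs."""

    fs: float = 2500.0
    n_epochs: int = 50
    n_electrodes: int = 64
    pre_s: float = 0.5
    post_s: float = 3.5
    oscillators: tuple[tuple[float, float], ...] = ((10.0, 1.0), (24.0, 1.2))
    erd_depth: float = 0.5  # fractional band-power drop during the task
    pink_scale: float = 1.0
    subject_id: str = "sub00"
    session_tag: str = "baseline"


@dataclass(frozen=True)
class BehaviorTable:
    """Per-subject retention score (dimensionless)."""

    scores: dict[str, float]

    def __post_init__(self):
        for k, v in self.scores.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite behavior score for {k!r}")

    def aligned(self, subject_ids) -> np.ndarray:
        return np.array([self.scores[s] for s in subject_ids])


@dataclass
class TFCohort:
    """A generated cohort: matched session TF maps plus the ground truth."""

    baseline: list[TFSeries]
    post: list[TFSeries]
    groups: list[str]
    truth: GroundTruth
    realized_effect: np.ndarray  # per-subject multiplicative band factor (CON: 1)
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def _smooth_unit_curve(rng: np.random.Generator, n: int, sigma_bins: float = 4.0) -> np.ndarray:
    """Smooth random curve with ~unit marginal variance (GP-like fingerprint)."""
    pad = int(4 * sigma_bins)
    z = rng.standard_normal(n + 2 * pad)
    k = np.exp(-0.5 * (np.arange(-pad, pad + 1) / sigma_bins) ** 2)
    k /= np.sqrt(np.sum(k ** 2))  # unit variance after convolution
    return np.convolve(z, k, mode="same")[pad:-pad]


def _erd_profile(n_electrodes: int, freqs: np.ndarray,
                 affected: tuple[int, ...]) -> np.ndarray:
    """Deterministic baseline ERD landscape (electrodes x freqs), values in (0, 1]."""
    w = np.full(n_electrodes, 0.4)
    w[list(affected)] = 1.0
    alpha = 0.30 * np.exp(-0.5 * ((freqs - 10.0) / 2.0) ** 2)
    beta = 0.40 * np.exp(-0.5 * ((freqs - 24.0) / 5.0) ** 2)
    return np.clip(1.0 - np.outer(w, alpha + beta), 0.2, None)


def _noise_sigma(freqs: np.ndarray, noise_sd: float) -> np.ndarray:
    # heavier multiplicative noise toward low frequencies (pink-noise residue)
    return noise_sd * (1.0 + 1.5 * np.exp(-(freqs - 1.0) / 6.0))


def simulate_tf_cohort(n_con: int = 12, n_exe: int = 12, n_timepoints: int = 300,
                       truth: GroundTruth | None = None, noise_sd: float = 0.25,
                       n_electrodes: int = 64) -> TFCohort:
    """Generate matched baseline/post TF maps for a two-group cohort.

    The cohort is a pure function of its arguments: all randomness derives
    from ``truth.seed`` through independent spawned streams.  Each subject's
    normalized power is the product of a deterministic ERD landscape, the
    subject's session-invariant spectral fingerprint, the planted band
    effect (post session of the EXE group only), and lognormal noise drawn
    independently per (electrode, frequency, timepoint).
    """
    if truth is None:
        truth = GroundTruth()
    if n_con < 2 or n_exe < 2:
        raise ValueError("need at least 2 subjects per group")
    if max(truth.affected_electrodes) >= n_electrodes:
        raise ValueError("affected electrode index out of range")
    freqs = DEFAULT_FREQS
    band = (freqs >= truth.band_lo) & (freqs <= truth.band_hi)
    profile = _erd_profile(n_electrodes, freqs, truth.affected_electrodes)
    sigma = _noise_sigma(freqs, noise_sd)[None, :, None]

    n_sub = n_con + n_exe
    groups = ["CON"] * n_con + ["EXE"] * n_exe
    subject_ids = [f"sub{i:02d}" for i in range(n_sub)]
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(truth.seed).spawn(n_sub + 1)]
    jitter_rng = streams[-1]

    realized = np.ones(n_sub)
    baseline_list, post_list = [], []
    effect_mask = np.zeros((n_electrodes, freqs.size), dtype=bool)
    effect_mask[np.ix_(list(truth.affected_electrodes), np.flatnonzero(band))] = True

    for i in range(n_sub):
        rng = streams[i]
        fingerprint = np.exp(
            truth.subject_confound_scale * _smooth_unit_curve(rng, freqs.size))
        mean_map = profile * fingerprint[None, :]
        if groups[i] == "EXE" and truth.effect_size != 1.0:
            realized[i] = 1.0 + (truth.effect_size - 1.0) * float(
                np.exp(RESPONSIVENESS_SD * jitter_rng.standard_normal()))
        else:
            jitter_rng.standard_normal()  # keep streams aligned across configs
        # session reactivity: smooth spectral curve, weighted independently
        # per electrode, applied to the post session only; uncorrelated with
        # group.  Real between-session state changes (vigilance, cap seating,
        # impedance drift) modulate mainly the alpha/low-beta range and are
        # heterogeneous across the scalp, so the curve is tapered by a
        # low-frequency envelope and carries a signed per-electrode weight.
        envelope = 1.0 / (1.0 + np.exp((freqs - 16.0) / 3.0))
        curve = _smooth_unit_curve(rng, freqs.size) * envelope
        elec_w = rng.standard_normal(n_electrodes)
        coh = truth.session_shift_coherence
        incoherent = np.outer(elec_w, curve)
        coherent = curve[None, :] + 0.5 * elec_w[:, None]
        shift = (1.0 - coh) * incoherent + coh * coherent
        post_map = mean_map * np.exp(truth.session_shift_scale * shift) \
            * np.where(effect_mask, realized[i], 1.0)
        for session_tag, m in (("baseline", mean_map), ("post", post_map)):
            noise = np.exp(sigma * rng.standard_normal((n_electrodes, freqs.size,
                                                        n_timepoints)))
            values = m[:, :, None] * noise
            tf = TFSeries(values=values, freqs=freqs.copy(), t0=0.5,
                          subject_id=subject_ids[i], session_tag=session_tag)
            (baseline_list if session_tag == "baseline" else post_list).append(tf)

    return TFCohort(baseline=baseline_list, post=post_list, groups=groups,
                    truth=truth, realized_effect=realized, subject_ids=subject_ids)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                fs: float) -> np.ndarray:
    """1/f-amplitude noise along the last axis via spectral shaping."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    amp[1:] = 1.0 / np.sqrt(f[1:])
    spec = (rng.standard_normal(shape + (f.size,))
            + 1j * rng.standard_normal(shape + (f.size,))) * amp
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std()


def simulate_raw_epochs(cfg: RawEpochConfig, truth: GroundTruth | None = None) -> EpochSet:
    """Simulate raw voltage epochs: pink background plus task-modulated oscillators.

    Each oscillator contributes a sinusoid (random phase per epoch) whose
    amplitude drops by ``sqrt(1 - erd_depth)`` after the cue, so task-window
    band power is ``(1 - erd_depth)`` times pre-cue power -- the classic ERD
    signature.  If ``truth`` is given and the session is a post session,
    oscillators inside the planted band have their ERD depth attenuated by
    ``effect_size`` (depth -> depth / effect_size).
    """
    if truth is None:
        truth = GroundTruth()
    if cfg.pre_s < 0.5 or cfg.post_s < 3.5:
        raise ValueError("epoch must span at least -0.5 s ... +3.5 s around the cue")
    if not 0.0 <= cfg.erd_depth < 1.0:
        raise ValueError("erd_depth must lie in [0, 1)")
    n = int(round((cfg.pre_s + cfg.post_s) * cfg.fs))
    onset = int(round(cfg.pre_s * cfg.fs))
    import zlib

    tag = zlib.crc32(f"{cfg.subject_id}|{cfg.session_tag}".encode())
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, tag]))
    data = cfg.pink_scale * _pink_noise(rng, (cfg.n_epochs, cfg.n_electrodes), n, cfg.fs)
    t = np.arange(n) / cfg.fs
    task = (np.arange(n) >= onset).astype(float)
    for f0, amp in cfg.oscillators:
        depth = cfg.erd_depth
        if (cfg.session_tag == "post" and truth.band_lo <= f0 <= truth.band_hi):
            depth = depth / truth.effect_size
        envelope = 1.0 - task * (1.0 - np.sqrt(max(1.0 - depth, 0.0)))
        phase = rng.uniform(0, 2 * np.pi, (cfg.n_epochs, cfg.n_electrodes, 1))
        spatial = 0.5 + rng.random((1, cfg.n_electrodes, 1))
        data += amp * spatial * envelope[None, None, :] * np.cos(
            2 * np.pi * f0 * t[None, None, :] + phase)
    return EpochSet(data=data, fs=cfg.fs, onset_index=onset,
                    subject_id=cfg.subject_id, session_tag=cfg.session_tag)


def simulate_behavior(cohort: TFCohort, noise_sd: float = 0.1,
                      slope: float = -1.0, intercept: float = 0.0) -> BehaviorTable:
    """Retention scores linearly tied to each subject's realized effect magnitude.

    ``score_s = intercept + slope * (realized_s - 1) + N(0, noise_sd)``.
    With ``noise_sd = 0`` the correlation between scores and realized effect
    magnitude is exactly +/-1 (sign of ``slope``).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([cohort.truth.seed, 0x0BE4]))
    mags = cohort.realized_effect - 1.0
    noise = rng.standard_normal(cohort.n_subjects) * noise_sd
    scores = intercept + slope * mags + noise
    return BehaviorTable(scores={sid: float(v)
                                 for sid, v in zip(cohort.subject_ids, scores)})
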