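# Methods

This note records the models, parameter choices, and numerical decisions
behind `erdscope`, and what the synthetic experiments do and do not show.

## Time-frequency preprocessing

Raw epochs (epochs × electrodes × samples, cue at `onset_index`) are
decomposed with complex Morlet wavelets, 1–55 Hz at 1 Hz resolution, wave
number (cycles) 7, via `mne.time_frequency.tfr_array_morlet`. Squared
magnitudes are normalized per epoch, electrode, and frequency by the mean
power in the 0.5 s window immediately before the cue; the ratio convention
keeps values positive and makes ERD read directly as values < 1 (dB and
percent-change variants are available as `mode=` options). Normalization is
applied per epoch before trial averaging for robustness to inter-trial
drift; normalizing the average instead is a config switch. The transform is
computed on the full epoch — reflect-padded when a low-frequency wavelet
(7 cycles at 1 Hz ≈ 11 s) exceeds the epoch — and the 0.5–3.5 s task
window is sliced afterwards, so wavelet edge effects stay outside the
retained samples. At the reference sampling rate of 2500 Hz the 3 s task
window gives 7500 timepoints per session, hence 7500 paired tuples per
subject and 2500 non-overlapping 3-frame topographic tensors.

## The paired adversarial classifier

Input tuples are (B_ts, A_ts): the 64 × 55 baseline and post-session
maps of one subject at one timepoint, labeled with the subject's group.
The pairing makes the classifier see each subject as their own baseline
control, removing the need to normalize post-session data across subjects.

**Architecture.** The feature extractor (Base CNN) applies convolutions
along the frequency axis only — frequency is ordered, electrode index is
not — with kernels of extent 1 along electrodes. The default time-frequency
architecture is one convolution block (8 channels, kernel 5, no pooling),
whose output (electrodes × channels × 51) is the attribution cue block,
followed by a dense embedding layer of width 64 that belongs to the
extractor, then two small multilayer heads (hidden widths 32 and 16): the
group head (2-way) and the subject adversary (S-way), deliberately of
similar capacity. All depths, widths, kernels and pooling factors are
config keys (`ArchConfig`); the topographic mode uses ordinary 2D
convolution blocks on 3 × 64 × 64 frame stacks.

Two considerations fixed the default depth. First, attribution resolution:
each extra conv+pool block widens the frequency receptive field (6 bins
for one pooled block, ~13 for two), and localizing a 3-bin planted band
through a 13-bin receptive field failed systematically. The single
unpooled block keeps the receptive field at 5 bins — matching the Simes
window length used downstream. Second, adversarial leverage: the
domain-confusion gradient only regularizes extractor parameters, so the
extractor must own enough capacity for the regularizer to matter; a
conv-only extractor (a few dozen parameters) leaves all memorization to
the heads, where the KL term cannot reach it. The dense embedding inside
the extractor is what gives the adversary something to remove.

**Losses and training.** All classifiers use the negative log-likelihood
of log-softmax outputs (log-sum-exp form, so zero probabilities cannot
occur). Per minibatch, the adversary first takes `adversary_steps` Adam
updates on its own NLL J_s with the extractor frozen (implemented by
detaching the shared feature difference, so each batch costs one extractor
forward/backward); then extractor and group head take one Adam update on
J_f = J_g + λ·KL(U‖h_s), with KL(U‖h) = −ln S − (1/S)Σ_k ln h_k ≥ 0.
The written objectives are sums over examples; reported values are
per-example means (the two differ only by a learning-rate rescaling).
Defaults: Adam at 1e-3 (3e-3 in the small-cohort benchmark), batch 128,
12 epochs. `keep_best=True` restores the parameters of the epoch with the
lowest validation group NLL — useful for the adversarial runs, whose
min-max dynamics can drift after finding a good solution. Training is a
pure function of (seed, data, config); divergence aborts with a diagnostic.

**The confusion equilibrium.** If the features carry group information, the
adversary can always concentrate its mass on the S′ subjects of the
predicted group, so with an effective adversary the subject loss settles
near −ln(1/S′) (≈ 2.6 for a 13-subject group: the level a maximally
confused 13-way classifier produces) rather than −ln(1/S). The KL term
conversely punishes *confident exclusion* of other-group subjects, which is
why very large λ destroys group discrimination as well — the usable λ
range is bounded on both sides, and `select_lambda` picks the largest λ
that keeps validation group accuracy above a floor while J_s sits nearest
−ln(1/S′).

**Cross-validation.** `timepoint_80_20` stratifies the 80/20 split per
subject (total train size exactly ⌊0.8 m⌋) and measures within-subject
generalization; `subject_leave2out_10fold` holds out one subject per group
per fold and measures transfer to unseen subjects. Two label-shuffling
controls are provided: per-tuple shuffling (training cannot converge —
neighboring timepoints are nearly identical but labeled inconsistently,
so accuracy stays at chance) and subject-level shuffling (group sizes
preserved; a selection-bias control).

## ccCAM

The channels c_i of the cue block computed on d = f(A) − f(B) are treated
as independent Gaussian cues to the classifier; with a trained network the
cue means are the observed maps (μ_i = c_i). Removing cue i (zeroing its
channel and re-running the embedding and group head) raises the
correct-class NLL from ε to ε_i, and under the Gaussian-cue model
ε_i − ε = μ_i²/(2σ_i²), giving the dataset-level precision estimate
1/σ_i² = Σ_j 2(ε_i − ε)⁽ʲ⁾ / ms(μ_i)⁽ʲ⁾, where ms is the mean square of
the (matrix-valued) cue map on example j. Numerical guards: per-example
contributions with ms below 1e-12 are skipped; negative contributions
(ablation improving the loss) are clamped to zero before summation,
preserving the nonnegative-precision contract (an unclamped diagnostic
mode exists); a cue with no valid contributions gets precision 0 and
weight 0; if all precisions vanish the weights fall back to uniform with a
warning. The combined map c* = Σ w_i μ_i uses w_i ∝ 1/σ_i², so Σ w_i = 1
by construction, and rescaling a cue map together with what the head
absorbs leaves c* invariant — the construction is insensitive to per-cue
feature scale.

The identity ε_i − ε = μ_i²/(2σ_i²) is exact in the confident-network
regime (cue means large against their spread); with strongly overlapping
class distributions the ratio estimator acquires a bias of order
3σ²/μ². The validation oracle therefore runs the 2-cue Gaussian toy with
μ/σ ≈ 10, where the estimated precision ratio converges to the analytic
inverse-variance ratio (cue-combination reliability weights) within a few
percent at n = 5000.

The combined map is returned to input resolution by linear interpolation
along the convolved axis at the receptive-field centers of the feature
bins (the electrode axis is never convolved in tf mode and is untouched);
edges are clamped to the outermost center. Frequency importance is the
CAM averaged over electrodes, per timepoint; the per-subject bootstrap
ratio BSR = mean_t / sd_t (sd guarded at 1e-12, guard hits logged) scores
each bin's attribution for temporal consistency, and group curves are
reported as mean ± standard error over subjects.

## Statistics

Subject-level BSR values are compared bin-wise (or pixel-wise) between
groups with one-way ANOVA (equivalent to the two-sample t-test, F = t²;
zero within-group variance falls back to the limit p of 0 or 1 with a
warning). Because neighboring bins are strongly dependent, raw p-values
are corrected with the Simes rule in a sliding window centered on each
bin: p′_j = min_i L·p_(i)/i over the window's order statistics, clipped at
1. Window length 5 for frequency curves and 3 × 3 for images, matching the
convolutional kernel extent — the scale over which attributions are
smeared. At array edges the window shrinks symmetrically and L is replaced
by the actual window size (a no-edge-correction variant is a config
switch). Significant bins are reported as maximal contiguous intervals
(1D) or 4-connected components (2D). Under the null (no planted effect)
the fraction of significant bins stays at the nominal α within Monte-Carlo
error (measured over 50 cohorts).

## The synthetic cohort generator

The generator defines the study conditions; every downstream claim is
relative to it. A subject-session map is the product of

* a deterministic ERD landscape: dips of depth 0.30 (alpha, center 10 Hz,
  σ 2 Hz) and 0.40 (beta, center 24 Hz, σ 5 Hz) over a sensorimotor
  electrode set (14 electrodes around C3/Cz/C4), 0.4-weighted elsewhere,
  floor 0.2;
* a per-subject spectral fingerprint exp(scale · smooth curve) — a
  GP-like gain over frequency (smoothing σ 4 bins, unit marginal
  variance), identical in both sessions; default scale 0.30;
* a per-subject *session reactivity* shift applied to the post session
  only: a smooth spectral curve tapered by a low-frequency envelope
  (logistic cutoff 16 Hz, width 3 Hz — between-session state changes such
  as vigilance, cap seating and impedance drift live mostly in the
  alpha/low-beta range), with per-electrode weighting. The
  `session_shift_coherence` parameter interpolates between
  scalp-heterogeneous shifts (0, the default: the curve carries an
  independent signed weight per electrode, the impedance/gel regime) and
  scalp-coherent shifts (1: one global curve plus a broadband electrode
  gain, the vigilance regime). Default scale 0.25. This term is what makes
  the paired difference carry subject identity: without it an
  unregularized classifier has no subject shortcut to take, and the
  adversary has nothing to do;
* the planted effect: post-session normalized power of the effect group
  multiplied by the subject's realized effect inside 27–29 Hz at the
  affected electrodes. Realized effects jitter log-normally (sd 0.25)
  around the nominal `effect_size` (default 1.35, i.e. a 35% ERD
  attenuation — the magnitude is a free parameter of the generator, chosen
  to be comfortably detectable at 12 + 12 subjects);
* i.i.d. lognormal per-timepoint noise whose log-sd grows toward low
  frequencies (× (1 + 1.5·e^{−(f−1)/6})), echoing the pink-noise character
  of raw EEG; default base sd 0.25.

Behavioral retention scores are a linear function of each subject's
realized (not nominal) effect magnitude plus Gaussian noise, so the
feature–behavior correlation is recoverable and exactly ±1 in the
noiseless limit. Raw voltage epochs (1/f spectral background plus
band-limited oscillators whose amplitude drops by √(1 − ERD depth) after
the cue) exercise the wavelet stage end to end. All randomness derives
from `GroundTruth.seed` through spawned, order-independent streams.

**What the generator does not emulate:** artifacts (blinks, EMG), volume
conduction and realistic spatial covariance, temporal autocorrelation of
the noise within a session, non-stationary effects across the task window,
and any biomechanical structure of the task. Passing tests therefore show
that the pipeline recovers a planted multiplicative band effect under
subject and session confounds of realistic magnitude — not that it would
survive real-data artifact structure.

## Validation experiments and their sizes

* **Band recovery:** 12 + 12 subjects × 300 timepoints, default
  architecture, λ = 1, 12 epochs (~2 minutes on one CPU). Checked across
  seeds: validation accuracy 0.92–0.98, the Simes-significant bins overlap
  27–29 Hz, and the peak group BSR difference falls inside the band.
* **Adversary benefit:** 8 + 8 subjects × 120 timepoints with
  scalp-coherent session shifts (scale 0.7), fingerprint scale 0.6 and
  effect 1.6 — conditions in which the subject shortcut is blatant and the
  band route clearly learnable — small architecture (2 conv channels,
  pooled, embedding 48), 4 leave-two-out folds, best-checkpoint selection,
  λ = 4 vs λ = 0, five cohort seeds (~6 minutes). Without the adversary
  the networks drive the training loss to zero by memorizing subjects and
  transfer at roughly chance; with it, mean held-out accuracy improves by
  ~20 percentage points.
* **Null calibration:** 50 effect-free cohorts, statistics stage only
  (~10 seconds).

These sizes are desk-scale choices; every count is a parameter and the
reference geometry (2500 Hz, 7500 timepoints) is exercised where it is
cheap (tiling counts, array geometry) rather than in the trained runs.

## Known limitations

* The attribution localizes to the kernel width (±2 bins), not to single
  bins; significant intervals are correspondingly wider than the planted
  band, and occasional spurious edge bins appear at the extremes of the
  frequency axis where the interpolation clamps.
* The precision estimator assumes the confident-network regime (see
  above); cue weights from a poorly trained network are not meaningful.
* The λ window between "adversary too weak to matter" and "group
  information destroyed" is data-dependent and can be narrow; the
  equilibrium diagnostics (J_s vs −ln(1/S′), KL trajectory) should be
  inspected, not assumed.
* Leave-two-out fold accuracies at 16 subjects are intrinsically noisy
  (each fold scores two subjects); benchmark conclusions are drawn from
  means over seeds and folds, never from single folds.
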