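# erdscope

Data-driven discovery of group-discriminative EEG spectral features with a
paired adversarial CNN, cue-combination class activation maps (ccCAM), and
sliding-window Simes statistics.

## The problem

Paired-session motor EEG studies ask which oscillatory features change
after an intervention: each subject performs a cued task before (baseline
session) and after (post session), and the question is which frequency
bands and scalp regions separate the intervention group (EXE) from controls
(CON). Classical analyses test a-priori bands (alpha 8–12 Hz, beta
15–29 Hz) at pre-selected electrodes and can miss narrower effects. With
only ~25 subjects, a classifier trained naively on such data does something
worse than overfitting: it memorizes *subjects* — every session pair
carries a stable per-subject spectral fingerprint that is far easier to
learn than the group effect — and then fails on held-out subjects.

`erdscope` implements a pipeline for this setting, exercised end to end on
a synthetic cohort generator with a planted, recoverable ground truth:

1. **Time-frequency maps** — Morlet wavelet power (wave number 7, 1–55 Hz
   at 1 Hz), normalized to the mean power in the 0.5 s pre-cue window,
   trial-averaged, and sliced to the 0.5–3.5 s task window. Each session
   becomes a 64 × 55 × T array of power ratios in which event-related
   desynchronization (ERD) reads directly as values below 1.
2. **Paired adversarial classifier** — a shared feature extractor f
   (convolutions along the frequency axis only) is applied to the baseline
   matrix B_ts and post matrix A_ts of the same subject s and timepoint t;
   the difference d = f(A) − f(B) feeds a group head h_t and a subject
   adversary h_s. The extractor minimizes the domain-confusion objective

       J_f = J_g + λ · Σ_i KL(U ‖ h_s(f(x_i))),

   pushing the adversary's output toward the uniform distribution U over
   subjects, which strips subject identity from the features and forces the
   group head onto features that transfer to unseen subjects.
3. **ccCAM attribution** — the channels of the final convolutional feature
   block are treated as independent Gaussian cues; each cue's precision is
   estimated by NLL ablation over the dataset
   (1/σ_i² = Σ_j 2(ε_i − ε)⁽ʲ⁾ / ms(μ_i)⁽ʲ⁾) and the class activation map
   is the precision-weighted combination c* = Σ w_i μ_i with
   w_i ∝ 1/σ_i². Per-frequency importance is summarized per subject by the
   bootstrap ratio (BSR): mean over timepoints / sd over timepoints.
4. **Statistics** — point-wise one-way ANOVA between the groups' BSR
   values, corrected with the Simes procedure in a sliding window
   (p′_j = min_i L·p_(i)/i, L = 5 for frequency curves, 3 × 3 for
   topographic maps), significance at α = 0.05.
5. **Topographic mode** — band-limited power projected to 64 × 64 scalp
   images (azimuthal-equidistant projection, Clough–Tocher cubic
   interpolation), stacked in 3-frame windows, classified with 2D
   convolutions, attributed with the same ccCAM/BSR/Simes chain.
6. **Baselines** — random forests (raw / frequency-weighted / band-binned),
   an RBF SVM, and CSP-derived features, run under fold plans byte-identical
   to the CNN's.

The networks are trained with a compact NumPy reverse-mode autodiff engine
(`erdscope.autodiff`), gradient-checked against finite differences, so the
package has no deep-learning framework dependency.

## Worked example

Simulate a 12-subject cohort (6 CON + 6 EXE, 150 timepoints) with an ERD
attenuation planted at 27–29 Hz over sensorimotor electrodes, train the
adversarial classifier, and run the attribution and statistics chain:

```python
import dataclasses
from erdscope.pipeline import RunConfig, run_pipeline

cfg = dataclasses.replace(RunConfig(), seed=1, n_con=6, n_exe=6,
                          n_timepoints=150, epochs=8)
summary = run_pipeline(cfg, "demo_run")
print(summary)
```

prints (a few minutes on one CPU):

```
"val_accuracy":            0.947
"significant_intervals_hz": [[23.0, 33.0], [53.0, 55.0]]
"planted_band_hz":         [27.0, 29.0]
"argmax_delta_bsr_hz":     27.0
"behavior_best_r":         0.948
```

Reading: the classifier separates the groups at 94.7% timepoint-level
validation accuracy; the Simes-corrected group comparison of the ccCAM BSR
curves flags 23–33 Hz (the planted 27–29 Hz band blurred by the width-5
frequency kernels, plus a small edge artifact at the top of the range); the
largest group BSR difference falls at 27 Hz, inside the planted band; and
the best time-averaged network feature correlates strongly with the
simulated retention scores, which were tied to each subject's realized
effect magnitude. `demo_run/` holds the cohort (HDF5), training history,
BSR curves and p-values (CSV); `erdscope report demo_run` renders the BSR
and p-value figures.

The same flow is available from the shell:

```bash
erdscope demo --seed 1 --out demo_run      # small end-to-end run + figures
erdscope simulate --seed 1 --out cohort.h5
erdscope run --config my_run.yaml --out results/
```

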