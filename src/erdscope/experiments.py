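"""Canned validation experiments exercising the pipeline end to end.

Each function generates its own inputs from a seed, runs the relevant part
of the pipeline, and returns plain numbers.  They are shared between the
test suite and the reproduction script so the quantities are computed in
exactly one place.
"""

from __future__ import annotations

import numpy as np

from . import bandstats, cccam, model, synthetic, tfmaps

__all__ = [
    "uniform_adversary_nll",
    "windowing_counts",
    "decomposition_geometry",
    "GaussianCueModel",
    "gaussian_cue_oracle",
    "band_recovery",
    "adversary_benefit",
    "null_calibration",
]


def uniform_adversary_nll(n_subjects: int = 13) -> float:
    """Subject NLL of a maximally-confused adversary over ``n_subjects``.

    Built through the loss module: a subject head with zeroed parameters
    emits uniform probabilities, so the measured J_s is the confusion
    equilibrium -ln(1/S).
    """
    arch = model.ArchConfig(conv_channels=(2,), pool=2, embed=(8,),
                            head_hidden=(4,))
    bundle = model.build_models(arch, n_subjects, seed=0, input_shape=(4, 55))
    for w, b in bundle.sub_layers:
        w.data[:] = 0.0
        b.data[:] = 0.0
    rng = np.random.default_rng(0)
    batch = (rng.random((8, 4, 55)), rng.random((8, 4, 55)),
             rng.integers(0, 2, 8), rng.integers(0, n_subjects, 8))
    _, J_s, _, _ = model.losses(bundle, batch)
    return float(J_s.data)


def windowing_counts(fs: float = 2500.0, task_seconds: float = 3.0,
                     frames_per_tensor: int = 3) -> dict:
    """Topographic tensor and tuple counts implied by the task window."""
    from . import topomaps

    T = int(task_seconds * fs)
    frames = np.zeros((T, 2, 2))
    tensors = topomaps.stack_frames(frames, k=frames_per_tensor)
    tf = tfmaps.TFSeries(values=np.ones((2, 55, T)), subject_id="s0",
                         session_tag="baseline")
    tf2 = tfmaps.TFSeries(values=np.ones((2, 55, T)), subject_id="s0",
                          session_tag="post")
    ds = tfmaps.build_pair_dataset([tf], [tf2], ["EXE"])
    return {"n_topo_tensors": len(tensors), "n_tuples_per_subject": ds.m}


def decomposition_geometry(seed: int = 0) -> dict:
    """Shape of a session TF map from simulated raw epochs (64 electrodes)."""
    cfg = synthetic.RawEpochConfig(fs=160.0, n_epochs=2, n_electrodes=64)
    epochs = synthetic.simulate_raw_epochs(cfg, synthetic.GroundTruth(seed=seed))
    tf = tfmaps.session_tf(epochs)
    return {"n_electrodes": tf.values.shape[0], "n_freq_bins": tf.values.shape[1]}


class GaussianCueModel:
    """Synthetic two-class classifier with exact Gaussian-cue likelihoods.

    The correct-class NLL is ``sum_i (c_i - m_i^y)^2 / (2 sigma_i^2)`` for
    cue values ``c_i`` with class means ``+/- m_i`` -- the generative model
    under which the cue-combination precision estimator is derived, hence
    the analytic oracle for it.
    """

    trained = True

    class arch:
        mode = "tf"

    def __init__(self, m, s2):
        self.m = np.asarray(m, float)
        self.s2 = np.asarray(s2, float)

    def group_nll_from_block(self, block, y):
        c = block.reshape(block.shape[0], -1)
        sign = np.where(np.asarray(y) == 1, 1.0, -1.0)[:, None]
        return ((c - sign * self.m) ** 2 / (2 * self.s2)).sum(axis=1)

    def sample(self, n, rng):
        y = rng.integers(0, 2, n)
        sign = np.where(y == 1, 1.0, -1.0)
        c = sign[:, None] * self.m + rng.standard_normal((n, self.m.size)) \
            * np.sqrt(self.s2)
        return c.reshape(n, self.m.size, 1, 1), y


def gaussian_cue_oracle(seed: int = 0, n: int = 5000,
                        m=(10.0, 10.0), s2=(1.0, 2.0)) -> dict:
    """Relative error of the estimated precision ratio on the 2-cue toy."""
    toy = GaussianCueModel(m, s2)
    mu, y = toy.sample(n, np.random.default_rng(seed))
    cueset = cccam.estimate_precisions_from_blocks(toy, mu, y)
    est = cueset.precisions[0] / cueset.precisions[1]
    true = s2[1] / s2[0]
    return {"precision_ratio_estimate": float(est),
            "precision_ratio_true": float(true),
            "precision_ratio_rel_error": float(abs(est - true) / true),
            "weight_sum_error": float(abs(cueset.weights.sum() - 1.0))}


def band_recovery(seed: int = 0, n_con: int = 12, n_exe: int = 12,
                  n_timepoints: int = 300, epochs: int = 12,
                  lam: float = 1.0) -> dict:
    """Full recovery experiment: train, attribute, test, localize.

    Returns the timepoint-level validation accuracy, the Simes-significant
    frequency bins, and the frequency of the largest group BSR difference,
    against the planted 27-29 Hz band.
    """
    truth = synthetic.GroundTruth(seed=seed)
    cohort = synthetic.simulate_tf_cohort(n_con, n_exe, n_timepoints, truth,
                                          noise_sd=0.25)
    ds = tfmaps.build_pair_dataset(cohort.baseline, cohort.post, cohort.groups)
    split = model.make_split(ds, "timepoint_80_20", seed=seed)
    bundle = model.build_models(model.ArchConfig(), ds.n_subjects, seed=seed,
                                lam=lam, input_shape=ds.baseline.shape[1:3])
    bundle, history = model.train(
        bundle, ds, split,
        model.TrainConfig(epochs=epochs, batch_size=128, lr=1e-3,
                          val_eval_cap=2000))
    bsr_map, cueset = cccam.frequency_bsr_pipeline(bundle, ds)
    y = ds.y_group
    p = bandstats.anova_pointwise(bsr_map.per_subject[y == 0],
                                  bsr_map.per_subject[y == 1])
    pmap = bandstats.PMap(p=p, p_corr=bandstats.simes_1d(p, 5), L=5)
    mask, intervals = bandstats.significant_regions(pmap)
    delta = np.abs(bsr_map.group_mean["EXE"] - bsr_map.group_mean["CON"])
    sig_hz = (np.flatnonzero(mask) + 1).tolist()
    band = [int(truth.band_lo), int(truth.band_hi)]
    return {
        "val_accuracy": history.val_acc[-1],
        "significant_bins_hz": sig_hz,
        "argmax_delta_bsr_hz": int(np.argmax(delta) + 1),
        "planted_band_hz": band,
        "band_overlap": bool(any(band[0] <= f <= band[1] for f in sig_hz)),
        "argmax_in_band": bool(band[0] <= np.argmax(delta) + 1 <= band[1]),
    }


#: Conditions of the subject-confound benchmark: a cohort whose post-session
#: shifts are scalp-coherent (a blatant low-dimensional subject signature)
#: with a clearly learnable planted band, so both the subject-shortcut and
#: the group-feature routes are available to the optimizer.
ADVERSARY_BENCH = dict(n_con=8, n_exe=8, n_timepoints=120, effect_size=1.6,
                       subject_confound_scale=0.6, session_shift_scale=0.7,
                       session_shift_coherence=1.0, noise_sd=0.25)


def _leave2out_accuracy(seed: int, lam: float, n_folds: int = 4,
                        epochs: int = 16) -> float:
    bench = ADVERSARY_BENCH
    truth = synthetic.GroundTruth(
        seed=seed, effect_size=bench["effect_size"],
        subject_confound_scale=bench["subject_confound_scale"],
        session_shift_scale=bench["session_shift_scale"],
        session_shift_coherence=bench["session_shift_coherence"])
    cohort = synthetic.simulate_tf_cohort(bench["n_con"], bench["n_exe"],
                                          bench["n_timepoints"], truth,
                                          noise_sd=bench["noise_sd"])
    ds = tfmaps.build_pair_dataset(cohort.baseline, cohort.post, cohort.groups)
    split = model.make_split(ds, "subject_leave2out_10fold", seed=seed,
                             n_folds=n_folds)
    arch = model.ArchConfig(conv_channels=(2,), pool=2, embed=(48,),
                            head_hidden=(16,))
    accs = []
    for fold in range(n_folds):
        bundle = model.build_models(arch, ds.n_subjects, seed=seed, lam=lam,
                                    input_shape=ds.baseline.shape[1:3])
        bundle, _ = model.train(
            bundle, ds, split,
            model.TrainConfig(epochs=epochs, batch_size=128, lr=3e-3,
                              val_eval_cap=320, keep_best=True), fold=fold)
        acc, _ = model.evaluate(bundle, ds, split.folds[fold][1][:320])
        accs.append(acc)
    return float(np.mean(accs))


def adversary_benefit(base_seed: int = 1, n_seeds: int = 5,
                      lam_tuned: float = 4.0) -> dict:
    """Leave-two-subjects-out accuracy with and without the adversary.

    Runs the benchmark on ``n_seeds`` cohorts (seeds ``base_seed ..
    base_seed + n_seeds - 1``) and reports the mean accuracies and their
    difference in percentage points.
    """
    acc0, acc1 = [], []
    for k in range(n_seeds):
        seed = base_seed + k
        acc0.append(_leave2out_accuracy(seed, 0.0))
        acc1.append(_leave2out_accuracy(seed, lam_tuned))
    return {
        "acc_lambda0": float(np.mean(acc0)),
        "acc_lambda_tuned": float(np.mean(acc1)),
        "gain_points": float(100 * (np.mean(acc1) - np.mean(acc0))),
        "per_seed_gain_points": [float(100 * (a - b))
                                 for a, b in zip(acc1, acc0)],
        "lam_tuned": lam_tuned,
    }


def null_calibration(seed: int = 0, n_cohorts: int = 50, n_con: int = 8,
                     n_exe: int = 8, n_timepoints: int = 40,
                     alpha: float = 0.05) -> dict:
    """False-positive rate of the ANOVA + sliding-Simes stage under the null.

    Cohorts are generated with ``effect_size = 1`` (no group effect); the
    per-subject statistic is the bootstrap ratio of the electrode-averaged
    session difference per frequency bin -- the statistics stage only, no
    model training.
    """
    fracs = []
    for k in range(n_cohorts):
        truth = synthetic.GroundTruth(effect_size=1.0, seed=seed * 100003 + k)
        cohort = synthetic.simulate_tf_cohort(n_con, n_exe, n_timepoints, truth,
                                              noise_sd=0.25)
        S = cohort.n_subjects
        per_subj = np.empty((S, 55))
        for i in range(S):
            diff = (cohort.post[i].values
                    - cohort.baseline[i].values).mean(axis=0).T  # (T, F)
            sd = np.maximum(diff.std(axis=0, ddof=1), 1e-12)
            per_subj[i] = diff.mean(axis=0) / sd
        y = np.array([g == "EXE" for g in cohort.groups], dtype=int)
        p = bandstats.anova_pointwise(per_subj[y == 0], per_subj[y == 1])
        pc = bandstats.simes_1d(p, 5)
        fracs.append(float(np.mean(pc < alpha)))
    fracs = np.array(fracs)
    mc_se = float(fracs.std(ddof=1) / np.sqrt(n_cohorts))
    return {"significant_fraction": float(fracs.mean()),
            "mc_se": mc_se,
            "bound": alpha + 3 * mc_se,
            "alpha": alpha,
            "n_cohorts": n_cohorts}
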