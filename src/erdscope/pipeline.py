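"""End-to-end runs: simulate -> pair -> train -> ccCAM -> statistics -> report.

A :class:`RunConfig` (YAML-loadable) names every parameter and seed; a run
directory holds the cohort, model history, BSR curves, corrected p-values
and a manifest (config hash + seeds) so any artifact can be regenerated
byte-identically under a fixed numerical environment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import bandstats, cccam, io, model, synthetic, tfmaps

__all__ = ["RunConfig", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Parameters of one reproducible run (desk-scale defaults)."""

    seed: int = 0
    n_con: int = 12
    n_exe: int = 12
    n_timepoints: int = 300
    band_lo: float = 27.0
    band_hi: float = 29.0
    effect_size: float = 1.35
    subject_confound_scale: float = 0.30
    session_shift_scale: float = 0.25
    noise_sd: float = 0.25
    lam: float = 1.0
    conv_channels: tuple[int, ...] = (8,)
    head_hidden: tuple[int, ...] = (32, 16)
    epochs: int = 12
    batch_size: int = 128
    split_strategy: str = "timepoint_80_20"
    alpha: float = 0.05
    simes_L: int = 5
    behavior_noise_sd: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("conv_channels", "head_hidden"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute the TF-map pipeline and write all artifacts to ``out_dir``.

    Returns a summary dict (validation accuracy, significant intervals,
    behavior correlation, paths).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = synthetic.GroundTruth(band_lo=cfg.band_lo, band_hi=cfg.band_hi,
                                  effect_size=cfg.effect_size,
                                  subject_confound_scale=cfg.subject_confound_scale,
                                  session_shift_scale=cfg.session_shift_scale,
                                  seed=cfg.seed)
    cohort = synthetic.simulate_tf_cohort(cfg.n_con, cfg.n_exe, cfg.n_timepoints,
                                          truth, noise_sd=cfg.noise_sd)
    behavior = synthetic.simulate_behavior(cohort, noise_sd=cfg.behavior_noise_sd)
    io.write_cohort(out / "cohort.h5", cohort, behavior)

    dataset = tfmaps.build_pair_dataset(cohort.baseline, cohort.post, cohort.groups)
    split = model.make_split(dataset, cfg.split_strategy, seed=cfg.seed)
    arch = model.ArchConfig(mode="tf", conv_channels=cfg.conv_channels,
                            head_hidden=cfg.head_hidden)
    bundle = model.build_models(arch, dataset.n_subjects, seed=cfg.seed, lam=cfg.lam,
                                input_shape=dataset.baseline.shape[1:3])
    tcfg = model.TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size)
    bundle, history = model.train(bundle, dataset, split, tcfg)

    import pandas as pd

    pd.DataFrame({"J_g": history.J_g, "J_s": history.J_s, "kl": history.kl,
                  "val_acc": history.val_acc}).to_csv(out / "history.csv",
                                                      index_label="epoch")

    bsr_map, cueset = cccam.frequency_bsr_pipeline(bundle, dataset)
    io.write_bsr_csv(out / "bsr.csv", dataset.freqs, bsr_map)

    y = dataset.y_group
    p_raw = bandstats.anova_pointwise(bsr_map.per_subject[y == 0],
                                      bsr_map.per_subject[y == 1])
    pmap = bandstats.PMap(p=p_raw, p_corr=bandstats.simes_1d(p_raw, cfg.simes_L),
                          L=cfg.simes_L, alpha=cfg.alpha)
    io.write_pmap_csv(out / "pvalues.csv", dataset.freqs, pmap)
    _, intervals = bandstats.significant_regions(pmap)

    feats = model.extract_features(bundle, dataset, f"top.{len(cfg.head_hidden)}")
    scores = behavior.aligned(dataset.subject_ids)
    best_r, best_c = 0.0, 0
    for c in range(feats.shape[1]):
        if np.std(feats[:, c]) == 0:
            continue
        r = model.feature_behavior_correlation(feats, scores, c)
        if abs(r) > abs(best_r):
            best_r, best_c = r, c

    summary = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "val_accuracy": history.val_acc[-1],
        "cue_weights": cueset.weights.tolist(),
        "significant_intervals_hz": [[float(dataset.freqs[a]), float(dataset.freqs[b])]
                                     for a, b in intervals],
        "planted_band_hz": [cfg.band_lo, cfg.band_hi],
        "argmax_delta_bsr_hz": float(dataset.freqs[int(np.argmax(np.abs(
            bsr_map.group_mean["EXE"] - bsr_map.group_mean["CON"])))]),
        "behavior_best_r": best_r,
        "behavior_best_component": best_c,
    }
    (out / "manifest.json").write_text(json.dumps(summary, indent=2))
    return summary


def make_report(run_dir) -> list[str]:
    """Render figures from a completed run directory; returns written paths.

    Missing artifacts produce warnings and a partial report rather than an
    error.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    run = Path(run_dir)
    written: list[str] = []

    bsr_path = run / "bsr.csv"
    if bsr_path.exists():
        df = pd.read_csv(bsr_path)
        fig, ax = plt.subplots(figsize=(7, 4))
        for g, color in (("CON", "tab:blue"), ("EXE", "tab:orange")):
            m, s = df[f"bsr_mean_{g}"], df[f"bsr_se_{g}"]
            ax.plot(df.freq_hz, m, color=color, label=g)
            ax.fill_between(df.freq_hz, m - s, m + s, color=color, alpha=0.3)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("BSR of ccCAM (mean ± SE)")
        ax.legend()
        fig.savefig(run / "bsr_curves.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(str(run / "bsr_curves.png"))
    else:
        warnings.warn("bsr.csv missing; skipping BSR figure", RuntimeWarning,
                      stacklevel=2)

    p_path = run / "pvalues.csv"
    if p_path.exists():
        df = pd.read_csv(p_path)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.semilogy(df.freq_hz, df.p_raw, label="raw p", alpha=0.6)
        ax.semilogy(df.freq_hz, df.p_simes, label="Simes-corrected p")
        ax.axhline(0.05, color="k", ls="--", lw=0.8)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("p-value")
        ax.legend()
        fig.savefig(run / "pvalues.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(str(run / "pvalues.png"))
    else:
        warnings.warn("pvalues.csv missing; skipping p-value figure", RuntimeWarning,
                      stacklevel=2)
    return written
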