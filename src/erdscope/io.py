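"""HDF5 / CSV serialization of cohorts and analysis artifacts."""

from __future__ import annotations

import numpy as np

from .synthetic import BehaviorTable, GroundTruth, TFCohort
from .tfmaps import TFSeries

__all__ = ["write_cohort", "read_cohort", "write_bsr_csv", "write_pmap_csv"]


def write_cohort(path, cohort: TFCohort, behavior: BehaviorTable | None = None) -> None:
    """Write a cohort to HDF5: /tf/{subject}/{session}, /labels, /truth, /behavior."""
    import h5py

    with h5py.File(path, "w") as f:
        for tf in cohort.baseline + cohort.post:
            f.create_dataset(f"tf/{tf.subject_id}/{tf.session_tag}",
                             data=tf.values.astype(np.float32), compression="gzip")
        lab = f.create_group("labels")
        lab.create_dataset("subject_ids",
                           data=np.array(cohort.subject_ids, dtype="S"))
        lab.create_dataset("groups", data=np.array(cohort.groups, dtype="S"))
        tr = f.create_group("truth")
        t = cohort.truth
        tr.attrs.update({"band_lo": t.band_lo, "band_hi": t.band_hi,
                         "effect_size": t.effect_size,
                         "subject_confound_scale": t.subject_confound_scale,
                         "seed": t.seed})
        tr.create_dataset("affected_electrodes",
                          data=np.asarray(t.affected_electrodes, dtype=np.int64))
        tr.create_dataset("realized_effect", data=cohort.realized_effect)
        if behavior is not None:
            bg = f.create_group("behavior")
            bg.create_dataset("subject_ids",
                              data=np.array(list(behavior.scores), dtype="S"))
            bg.create_dataset("scores",
                              data=np.array(list(behavior.scores.values())))


def read_cohort(path) -> tuple[TFCohort, BehaviorTable | None]:
    import h5py

    with h5py.File(path, "r") as f:
        subject_ids = [s.decode() for s in f["labels/subject_ids"][()]]
        groups = [s.decode() for s in f["labels/groups"][()]]
        tr = f["truth"]
        truth = GroundTruth(
            band_lo=float(tr.attrs["band_lo"]), band_hi=float(tr.attrs["band_hi"]),
            affected_electrodes=tuple(int(i) for i in tr["affected_electrodes"][()]),
            effect_size=float(tr.attrs["effect_size"]),
            subject_confound_scale=float(tr.attrs["subject_confound_scale"]),
            seed=int(tr.attrs["seed"]))
        baseline, post = [], []
        for sid in subject_ids:
            for tag, dest in (("baseline", baseline), ("post", post)):
                dest.append(TFSeries(values=f[f"tf/{sid}/{tag}"][()].astype(float),
                                     subject_id=sid, session_tag=tag))
        behavior = None
        if "behavior" in f:
            ids = [s.decode() for s in f["behavior/subject_ids"][()]]
            behavior = BehaviorTable(scores=dict(zip(ids, f["behavior/scores"][()])))
        realized = tr["realized_effect"][()]
    return TFCohort(baseline=baseline, post=post, groups=groups, truth=truth,
                    realized_effect=realized, subject_ids=subject_ids), behavior


def write_bsr_csv(path, freqs, bsr_map) -> None:
    """Frequency, per-group mean BSR and standard error."""
    import pandas as pd

    df = pd.DataFrame({"freq_hz": np.asarray(freqs)})
    for g in bsr_map.group_mean:
        df[f"bsr_mean_{g}"] = bsr_map.group_mean[g]
        df[f"bsr_se_{g}"] = bsr_map.group_se[g]
    df.to_csv(path, index=False)


def write_pmap_csv(path, freqs, pmap) -> None:
    import pandas as pd

    pd.DataFrame({"freq_hz": np.asarray(freqs), "p_raw": pmap.p,
                  "p_simes": pmap.p_corr,
                  "significant": pmap.p_corr < pmap.alpha}).to_csv(path, index=False)
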