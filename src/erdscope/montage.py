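"""Electrode montages: standard layouts, validation, and TSV round-trip.

A montage is the scalp geometry the topographic stage projects from: a list
of electrode labels plus 3D head-frame coordinates on (roughly) a unit
sphere.  Standard layouts are taken from the montage definitions bundled
with :mod:`mne` so the 64-channel cap used throughout the package matches a
real recording cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ElectrodeLayout", "make_layout", "write_layout_tsv", "read_layout_tsv"]

#: mne standard montages with exactly the requested channel count (non-64 sizes,
#: used for small test geometries).
_SUPPORTED = {16: "biosemi16", 32: "biosemi32", 128: "biosemi128"}

#: 64-channel extended 10-20 cap (actiCAP-64 style, FCz reference not recorded).
_CAP64 = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 FC5 FC1 FC2 FC6 T7 C3 Cz C4 T8 TP9 CP5 CP1 CP2 "
    "CP6 TP10 P7 P3 Pz P4 P8 PO9 O1 Oz O2 PO10 AF7 AF3 AF4 AF8 F5 F1 F2 F6 "
    "FT9 FT7 FC3 FC4 FT8 FT10 C5 C1 C2 C6 TP7 CP3 CPz CP4 TP8 P5 P1 P2 P6 "
    "PO7 PO3 POz PO4 PO8"
).split()

#: mne montages are in metres; head radius is ~9.5 cm.  Rescale so the
#: electrode shell sits near norm 1, which the validation contract expects.
_HEAD_RADIUS_M = 0.095


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode labels and unit-sphere-scale 3D positions (x right, y front, z up)."""

    labels: tuple[str, ...]
    pos3d: np.ndarray  # (n, 3)

    def __post_init__(self):
        pos = np.asarray(self.pos3d, dtype=float)
        if len(self.labels) != pos.shape[0]:
            raise ValueError("label count must equal coordinate count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode coordinates must be finite")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms <= 0) or np.any(norms > 1.5):
            raise ValueError("electrode norms must lie in (0, 1.5]")
        object.__setattr__(self, "pos3d", pos)

    def __len__(self) -> int:
        return len(self.labels)


def make_layout(n_electrodes: int = 64) -> ElectrodeLayout:
    """Return a deterministic standard cap layout with ``n_electrodes`` channels.

    The 64-channel layout is an extended 10-20 cap (actiCAP-64 label set,
    positions from mne's standard 10-05 head).  Sizes 16/32/128 come from the
    corresponding biosemi montages; any other count raises ``ValueError``.
    """
    import warnings

    import mne

    if n_electrodes == 64:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            mont = mne.channels.make_standard_montage("standard_1020")
        pos = mont.get_positions()["ch_pos"]
        labels = tuple(_CAP64)
    elif n_electrodes in _SUPPORTED:
        mont = mne.channels.make_standard_montage(_SUPPORTED[n_electrodes])
        pos = mont.get_positions()["ch_pos"]
        labels = tuple(mont.ch_names)
    else:
        raise ValueError(
            f"no supported standard montage with {n_electrodes} electrodes; "
            f"choose one of {sorted(set(_SUPPORTED) | {64})}"
        )
    coords = np.array([pos[ch] for ch in labels]) / _HEAD_RADIUS_M
    return ElectrodeLayout(labels=labels, pos3d=coords)


def write_layout_tsv(layout: ElectrodeLayout, path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tx\ty\tz\n")
        for lab, (x, y, z) in zip(layout.labels, layout.pos3d):
            fh.write(f"{lab}\t{x:.8f}\t{y:.8f}\t{z:.8f}\n")


def read_layout_tsv(path) -> ElectrodeLayout:
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("label"):
            raise ValueError("montage TSV must start with a 'label\\tx\\ty\\tz' header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"malformed montage row: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return ElectrodeLayout(labels=tuple(labels), pos3d=np.array(rows))
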