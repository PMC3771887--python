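"""Idealized spherical montage for the modified 10-20 recording layout.

The recording used 63 Ag/AgCl scalp electrodes plus two horizontal and two
vertical bipolar EOG channels.  Analyses run on the 61 scalp channels
(excluding the ear electrodes A1/A2) and, for the mass-univariate test, on a
34-channel subset giving even full-head coverage.

Positions are generated on the unit sphere from the standard 10-20 geometry:
the outer ring (Fp*/AF7/F7/FT7/T7/TP7/P7/PO7/O* and right homologs) sits 18
degrees above the equatorial plane, midline electrodes every 18 degrees along
the nasion-inion arc, and lateral electrodes by spherical interpolation
between the midline and the outer-ring end of their coronal row.  This gives
deterministic coordinates with exact left/right mirror symmetry; only relative
geometry (inter-electrode distances) matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 63 scalp electrode labels, in recording order.
CHANNELS_63: tuple[str, ...] = (
    "AF7", "Fp1", "Fpz", "Fp2", "AF8", "AF3", "AFz", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "A1", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "A2",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Bipolar EOG channels: two horizontal (outer canthi), two vertical (above /
#: below the left eye).
EOG_CHANNELS: tuple[str, ...] = ("HEOGL", "HEOGR", "VEOGU", "VEOGD")

#: Scalp channels entering analysis (ear electrodes A1/A2 excluded).
ANALYSIS_61: tuple[str, ...] = tuple(c for c in CHANNELS_63 if c not in ("A1", "A2"))

#: Default 34-channel even-coverage subset for the mass-univariate test.
#: Includes every electrode named in the results (TP7, P7, P4, F7, CP1, P1,
#: CPz, Pz, CP2, P2).
SUBSET_34: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP1", "CPz", "CP2", "TP8",
    "P7", "P3", "P1", "Pz", "P2", "P4", "P8",
    "PO7", "O1", "Oz", "O2", "PO8",
)

#: Centro-parietal ROIs for the P3b mean-amplitude analysis.
ROIS: dict[str, tuple[str, ...]] = {
    "left": ("CP1", "P1"),
    "middle": ("CPz", "Pz"),
    "right": ("CP2", "P2"),
}

FRONTAL_CHANNELS: tuple[str, ...] = ("AF7", "Fp1", "Fpz", "Fp2", "AF8")

# Outer ring: azimuth (degrees clockwise from the front midline, right
# positive) of the 10%-ring electrodes, all at polar angle 72 deg from vertex.
_OUTER_RING = {
    "Fpz": 0.0, "Fp2": 18.0, "AF8": 36.0, "F8": 54.0, "FT8": 72.0,
    "T8": 90.0, "TP8": 108.0, "P8": 126.0, "PO8": 144.0, "O2": 162.0,
    "Oz": 180.0,
    "O1": -162.0, "PO7": -144.0, "P7": -126.0, "TP7": -108.0, "T7": -90.0,
    "FT7": -72.0, "F7": -54.0, "AF7": -36.0, "Fp1": -18.0,
}

# Midline electrodes: signed polar angle along the nasion-inion arc
# (positive = anterior).
_MIDLINE = {"AFz": 54.0, "Fz": 36.0, "FCz": 18.0, "Cz": 0.0,
            "CPz": -18.0, "Pz": -36.0, "POz": -54.0}

# Inner rows: (midline label, left ring end, right ring end).
_ROWS = {
    "AF": ("AFz", "AF7", "AF8"),
    "F": ("Fz", "F7", "F8"),
    "FC": ("FCz", "FT7", "FT8"),
    "C": ("Cz", "T7", "T8"),
    "CP": ("CPz", "TP7", "TP8"),
    "P": ("Pz", "P7", "P8"),
    "PO": ("POz", "PO7", "PO8"),
}

_RING_THETA = 72.0  # outer-ring polar angle from the vertex


def _sph(theta_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector at polar angle theta from +z, azimuth from front midline.

    Axes: +x right, +y anterior, +z up.
    """
    th = np.deg2rad(theta_deg)
    az = np.deg2rad(azim_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - frac) * omega) * a + np.sin(frac * omega) * b) / np.sin(omega)


def _build_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for name, az in _OUTER_RING.items():
        pos[name] = _sph(_RING_THETA, az)
    for name, ap in _MIDLINE.items():
        pos[name] = _sph(abs(ap), 0.0 if ap >= 0 else 180.0)
    for row, (mid, left_end, right_end) in _ROWS.items():
        for digit in (1, 2, 3, 4, 5, 6):
            name = f"{row}{digit}"
            if name not in CHANNELS_63:
                continue
            frac = np.ceil(digit / 2) / 4.0  # 1,2 -> 1/4; 3,4 -> 1/2; 5,6 -> 3/4
            end = pos[right_end] if digit % 2 == 0 else pos[left_end]
            pos[name] = _slerp(pos[mid], end, frac)
    # Ear electrodes just below the equatorial plane.
    pos["A1"] = _sph(100.0, -90.0)
    pos["A2"] = _sph(100.0, 90.0)
    # EOG: outer canthi (horizontal) and above/below the left eye (vertical).
    pos["HEOGL"] = _sph(105.0, -40.0)
    pos["HEOGR"] = _sph(105.0, 40.0)
    pos["VEOGU"] = _sph(95.0, -15.0)
    pos["VEOGD"] = _sph(115.0, -15.0)
    return {k: v / np.linalg.norm(v) for k, v in pos.items()}


@dataclass(frozen=True)
class Montage:
    """Channel names, unit-sphere positions, and channel classes (EEG/EOG)."""

    names: tuple[str, ...]
    pos: np.ndarray  # (n_channels, 3), unit-normalized
    kinds: tuple[str, ...]  # "EEG" | "EOG" per channel
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def position(self, name: str) -> np.ndarray:
        try:
            return self.pos[self._index[name]]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}") from None

    def positions(self, names) -> np.ndarray:
        return np.stack([self.position(n) for n in names])

    def eeg_names(self) -> tuple[str, ...]:
        return tuple(n for n, k in zip(self.names, self.kinds) if k == "EEG")

    def distances(self, names=None) -> np.ndarray:
        """Pairwise chord distances on the unit sphere."""
        p = self.pos if names is None else self.positions(names)
        d = p[:, None, :] - p[None, :, :]
        return np.sqrt((d ** 2).sum(-1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": list(self.names),
            "x": self.pos[:, 0], "y": self.pos[:, 1], "z": self.pos[:, 2],
            "class": list(self.kinds),
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Montage":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df["name"]), df[["x", "y", "z"]].to_numpy(float),
                   tuple(df["class"]))


def make_montage() -> Montage:
    """Deterministic idealized montage: 63 scalp + 4 EOG channels."""
    table = _build_positions()
    names = CHANNELS_63 + EOG_CHANNELS
    pos = np.stack([table[n] for n in names])
    kinds = tuple("EEG" if n in CHANNELS_63 else "EOG" for n in names)
    return Montage(names, pos, kinds)
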