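"""Epoch and ERP containers with HDF5 round-trip I/O.

An :class:`EpochSet` holds one subject's segmented trials as a
(trials, channels, samples) float array in microvolts together with the time
axis (ms), sampling rate, per-trial condition labels and channel metadata.
A :class:`SubjectERP` holds that subject's per-condition trial averages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np


def default_times(sfreq: float = 500.0, tmin_ms: float = -100.0,
                  n_samples: int = 500) -> np.ndarray:
    """Epoch time axis in ms: -100 ... 898 at 500 Hz by default."""
    step = 1000.0 / sfreq
    return tmin_ms + step * np.arange(n_samples)


@dataclass
class EpochSet:
    data: np.ndarray          # (n_trials, n_channels, n_samples), microvolts
    times: np.ndarray         # (n_samples,), ms
    sfreq: float
    conditions: np.ndarray    # (n_trials,), condition label per trial
    ch_names: tuple[str, ...]
    ch_kinds: tuple[str, ...]  # "EEG" | "EOG"
    subject: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions)
        n_tr, n_ch, n_sa = self.data.shape
        if len(self.times) != n_sa:
            raise ValueError("times length does not match data samples")
        if len(self.conditions) != n_tr:
            raise ValueError("conditions length does not match trial count")
        if len(self.ch_names) != n_ch or len(self.ch_kinds) != n_ch:
            raise ValueError("channel metadata does not match data channels")
        steps = np.diff(self.times)
        if len(steps) and not np.allclose(steps, 1000.0 / self.sfreq, atol=1e-6):
            raise ValueError("times must be uniform at 1000/sfreq ms")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def eeg_mask(self) -> np.ndarray:
        return np.array([k == "EEG" for k in self.ch_kinds])

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), times=self.times.copy(),
                       conditions=self.conditions.copy())

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        return replace(self, data=self.data[idx], conditions=self.conditions[idx])


@dataclass
class SubjectERP:
    """Per-condition channel x sample averages for one subject."""

    data: dict[str, np.ndarray]   # condition -> (n_channels, n_samples)
    n_trials: dict[str, int]
    times: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    subject: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for cond, arr in self.data.items():
            if arr.shape != (len(self.ch_names), len(self.times)):
                raise ValueError(f"condition {cond}: shape {arr.shape} does not "
                                 f"match channels x times")
            if self.n_trials.get(cond, 0) < 1:
                raise ValueError(f"condition {cond}: needs >= 1 trial")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.data)

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def copy(self) -> "SubjectERP":
        return SubjectERP({c: a.copy() for c, a in self.data.items()},
                          dict(self.n_trials), self.times.copy(), self.sfreq,
                          tuple(self.ch_names), self.subject)


def save_epochs(path, epochs: EpochSet) -> None:
    """Write an EpochSet to HDF5 (float32 data, string tables, attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("conditions",
                         data=np.array(epochs.conditions, dtype="S8"))
        f.create_dataset("ch_names", data=np.array(epochs.ch_names, dtype="S16"))
        f.create_dataset("ch_kinds", data=np.array(epochs.ch_kinds, dtype="S8"))
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["subject"] = epochs.subject


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()].astype(float),
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            conditions=f["conditions"][()].astype(str),
            ch_names=tuple(f["ch_names"][()].astype(str)),
            ch_kinds=tuple(f["ch_kinds"][()].astype(str)),
            subject=int(f.attrs["subject"]),
        )
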