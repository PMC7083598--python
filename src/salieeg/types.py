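"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class Recording:
    """Continuous multichannel neural time series.

    data is channels x samples in microvolts. ``groups`` names channel
    subsets ("central": electrodes around Cz, "frontal": around Fz); all
    group members must be present in ``labels``. ``reference`` records the
    referencing state ("raw" or "average").
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    groups: dict[str, list[str]] = field(default_factory=dict)
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label count must match channel count")
        for g, members in self.groups.items():
            missing = set(members) - set(self.labels)
            if missing:
                raise ValueError(f"group {g!r} members not in labels: {missing}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([pos[n] for n in names], dtype=int)

    def group_union_index(self) -> np.ndarray:
        """Indices of the union of the central and frontal groups.

        Statistical contrasts are computed over this electrode set.
        """
        names: list[str] = []
        for g in ("central", "frontal"):
            for n in self.groups.get(g, []):
                if n in self.labels and n not in names:
                    names.append(n)
        if not names:  # fall back to every non-EOG channel
            names = [n for n in self.labels if not n.upper().startswith("EOG")]
        return self.channel_index(names)

    def pick(self, names: Sequence[str]) -> "Recording":
        idx = self.channel_index(names)
        groups = {g: [n for n in m if n in names] for g, m in self.groups.items()}
        return Recording(self.data[idx], self.fs, list(names), groups,
                         self.reference)

    def drop(self, names: Sequence[str]) -> "Recording":
        keep = [n for n in self.labels if n not in set(names)]
        return self.pick(keep)

    def copy_with(self, data: np.ndarray, **kw) -> "Recording":
        rec = replace(self, data=data, **kw)
        return rec


@dataclass
class Epochs:
    """Onset-aligned trials x channels x samples with per-trial metadata.

    ``window`` is (start, stop) in seconds relative to onset, [-5, +5] by
    default. ``meta`` carries one row per trial with at least columns
    kind ('target' | 'salient' | 'control'), tier, scene, subject and
    onset_time.
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    meta: pd.DataFrame
    labels: list[str]
    groups: dict[str, list[str]] = field(default_factory=dict)

    KINDS = ("target", "salient", "control")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta rows must match trial count")
        bad = set(self.meta["kind"]) - set(self.KINDS)
        if bad:
            raise ValueError(f"unknown trial kinds: {bad}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def onset_sample(self) -> int:
        return int(round(-self.window[0] * self.fs))

    def select(self, **conditions) -> "Epochs":
        mask = np.ones(len(self.meta), dtype=bool)
        for col, val in conditions.items():
            mask &= np.asarray(self.meta[col] == val)
        return Epochs(self.data[mask], self.fs, self.window,
                      self.meta[mask].reset_index(drop=True),
                      self.labels, self.groups)

    def group_union_index(self) -> np.ndarray:
        rec = Recording(np.zeros((len(self.labels), 1)), self.fs,
                        self.labels, self.groups)
        return rec.group_union_index()

    @staticmethod
    def concatenate(parts: Sequence["Epochs"]) -> "Epochs":
        parts = [p for p in parts if p.n_trials > 0]
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.labels != first.labels or p.window != first.window:
                raise ValueError("epoch parts are not compatible")
        return Epochs(np.concatenate([p.data for p in parts], axis=0),
                      first.fs, first.window,
                      pd.concat([p.meta for p in parts], ignore_index=True),
                      first.labels, first.groups)


@dataclass
class SalienceCurve:
    """Behavioral salience time course of one scene, values in [0, 1]."""

    values: np.ndarray
    fs: float
    scene: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs


@dataclass
class EnvelopeTrace:
    """Acoustic envelope of one scene (arbitrary positive units)."""

    values: np.ndarray
    fs: float
    scene: int = 0


@dataclass
class Leadfield:
    """Channels x voxels gain matrix mapping sources to sensors."""

    gain: np.ndarray
    positions: np.ndarray | None = None   # voxels x 3, for reporting only

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[1]
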