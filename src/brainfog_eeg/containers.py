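"""Core in-memory containers shared across the pipeline.

All signal data is stored in microvolts as ``channels x samples`` (or
``trials x channels x samples`` for epoched data) float arrays.  Containers
are lightweight dataclasses; operations that transform them live in the
stage modules (:mod:`.preprocess`, :mod:`.avalanche`, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["Montage", "Recording", "Epochs", "Erp"]


@dataclass(frozen=True)
class Montage:
    """Electrode montage: names, 3-D positions, and projected 2-D radius.

    The radius follows the topographic-plot convention used by common EEG
    toolboxes: angle from the vertex divided by pi, so the head-circumference
    line (equator) sits at radius 0.5 and electrodes below it (cheeks, neck)
    have radius > 0.5.
    """

    table: pd.DataFrame  # columns: name, x, y, z, radius

    def __post_init__(self) -> None:
        required = {"name", "x", "y", "z", "radius"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"montage table missing columns: {sorted(missing)}")
        if self.table["name"].duplicated().any():
            dupes = self.table["name"][self.table["name"].duplicated()].tolist()
            raise ValueError(f"duplicate channel names in montage: {dupes}")
        if not np.isfinite(self.table["radius"].to_numpy(dtype=float)).all():
            raise ValueError("montage radii must be finite")

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def radius_of(self, name: str) -> float:
        row = self.table.loc[self.table["name"] == name, "radius"]
        if row.empty:
            raise KeyError(f"channel {name!r} not in montage")
        return float(row.iloc[0])

    def subset(self, names: list[str]) -> "Montage":
        tab = self.table.set_index("name").loc[names].reset_index()
        return Montage(tab)

    def scalp_names(self, radius_max: float = 0.5) -> list[str]:
        keep = self.table["radius"] <= radius_max
        return self.table.loc[keep, "name"].tolist()


@dataclass
class Recording:
    """A continuous multichannel recording.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One name per row of ``data``.
    montage
        Optional :class:`Montage` covering at least the recording's channels.
    subject_id, cohort_label
        Subject metadata (cohort in {"A", "B", "C"} for the study design).
    meta
        Free-form provenance (generator parameters, pipeline history, ...).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    montage: Montage | None = None
    subject_id: str = ""
    cohort_label: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes: Any) -> "Recording":
        """Shallow functional update; data arrays are not copied unless passed."""
        out = replace(self, **changes)
        return out


@dataclass
class Epochs:
    """Stimulus-locked trials: ``(n_trials, n_channels, n_times)`` microvolts."""

    data: np.ndarray
    fs: float
    tmin_ms: float
    tmax_ms: float
    channel_names: list[str]
    condition_codes: list[str]
    baseline_window_ms: tuple[float, float] | None = None
    subject_id: str = ""
    cohort_label: str = ""
    paradigm: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Epochs.data must be 3-D (trials x channels x times)")
        if not (self.tmin_ms < 0 <= self.tmax_ms):
            raise ValueError(
                f"epoch window must straddle the stimulus: tmin={self.tmin_ms}, "
                f"tmax={self.tmax_ms}"
            )
        n_expected = int(round((self.tmax_ms - self.tmin_ms) * self.fs / 1000.0))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"time axis length {self.data.shape[2]} != "
                f"round((tmax-tmin)*fs/1000) = {n_expected}"
            )
        if len(self.condition_codes) != self.data.shape[0]:
            raise ValueError("one condition code per trial required")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("one channel name per channel required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + 1000.0 * np.arange(self.n_times) / self.fs

    def select_conditions(self, codes: set[str] | list[str]) -> "Epochs":
        codes = set(codes)
        keep = [i for i, c in enumerate(self.condition_codes) if c in codes]
        if not keep:
            raise ValueError(f"no trials with condition codes {sorted(codes)}")
        return replace(
            self,
            data=self.data[keep],
            condition_codes=[self.condition_codes[i] for i in keep],
        )

    def average(self) -> np.ndarray:
        """Per-channel trial average, ``(n_channels, n_times)``."""
        return self.data.mean(axis=0)


@dataclass
class Erp:
    """A grand-average waveform: ``(n_channels, n_times)`` microvolts."""

    waveform: np.ndarray
    fs: float
    tmin_ms: float
    channel_names: list[str]
    cohort_label: str = ""
    condition: str = ""
    n_subjects: int = 0
    n_trials_total: int = 0

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 2:
            raise ValueError("Erp.waveform must be 2-D (channels x times)")
        if not np.isfinite(self.waveform).all():
            raise ValueError("Erp waveform contains non-finite values")
        if len(self.channel_names) != self.waveform.shape[0]:
            raise ValueError("one channel name per waveform row required")

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + 1000.0 * np.arange(self.waveform.shape[1]) / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"electrode {name!r} not present in Erp") from None
        return self.waveform[idx]
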