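"""Shared containers for PPG records and stressor schedules."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("green", "blue", "ir", "red")
STRESSORS = ("CP", "HG")


@dataclass
class PpgRecord:
    """One subject's raw multi-wavelength PPG.

    ``data`` holds columns ``time, green, blue, ir, red``; ``fs`` is the
    nominal sampling rate in Hz.
    """

    fs: float
    data: pd.DataFrame
    subject_id: str = "s000"

    def __post_init__(self) -> None:
        missing = [c for c in ("time",) + CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"PpgRecord missing columns: {missing}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return self.data[name].to_numpy()


@dataclass
class EventSchedule:
    """Ordered stressor epochs as ``(label, onset_s, end_s)`` tuples."""

    epochs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = -np.inf
        for label, onset, end in self.epochs:
            if end <= onset:
                raise ValueError(f"epoch {label}: end {end} <= onset {onset}")
            if onset < prev_end:
                raise ValueError(f"epoch {label}: overlaps previous epoch")
            prev_end = end

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs, columns=["stressor", "onset_s", "end_s"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventSchedule":
        return cls([(str(r.stressor), float(r.onset_s), float(r.end_s))
                    for r in df.itertuples()])
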