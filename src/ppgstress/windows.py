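"""Stressor phase windows and the per-window feature table.

Each stressor epoch contributes four analysis windows of the AC series:
baseline (the 2 min before onset), the first and second minute of the
stressor, and recovery (the 2 min after the end). All windows are half-open
``[start, end)`` time intervals — a beat exactly on a boundary belongs to
the later window — so no beat is ever counted twice.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import (DEFAULT_K_MAX, DEFAULT_M, DEFAULT_R_FRAC,
                       DEFAULT_R_RESOLUTION, compute_features)
from .fiducials import AcSeries
from .types import EventSchedule

log = logging.getLogger(__name__)

PHASES = ("baseline", "min1", "min2", "recovery")


@dataclass
class PhaseWindow:
    label: str
    span: tuple
    values: np.ndarray
    truncated: bool = False

    @property
    def n_beats(self) -> int:
        return len(self.values)


@dataclass
class PhaseWindows:
    baseline: PhaseWindow
    min1: PhaseWindow
    min2: PhaseWindow
    recovery: PhaseWindow

    def __iter__(self):
        return iter((self.baseline, self.min1, self.min2, self.recovery))


def build_event_signal(schedule: EventSchedule, duration_s: float, fs: float) -> np.ndarray:
    """0/1 sample series: 1 while a stressor is on (half-open epochs)."""
    schedule.validate()
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    out = np.zeros(n, dtype=int)
    for label, onset, end in schedule.epochs:
        if onset < 0 or end > duration_s:
            raise ValueError(f"epoch {label} [{onset}, {end}) outside the record")
        out[(t >= onset) & (t < end)] = 1
    return out


def extract_phase_windows(ac: AcSeries, epoch: tuple,
                          duration_s: float | None = None) -> PhaseWindows:
    """The four phase windows of one stressor epoch, from kept beats only.

    ``duration_s`` bounds the recovery span; windows cut short by the end of
    the record carry a truncation flag.
    """
    label, onset, end = epoch
    if len(ac.beat_times) == 0:
        raise ValueError("empty AC series")
    if onset < 120.0:
        raise ValueError("baseline window needs 120 s of record before stressor onset")
    if duration_s is None:
        duration_s = float(ac.beat_times[-1])
    t = ac.kept_times
    v = ac.kept_values
    spans = {
        "baseline": (onset - 120.0, onset),
        "min1": (onset, onset + 60.0),
        "min2": (onset + 60.0, onset + 120.0),
        "recovery": (end, end + 120.0),
    }
    windows = {}
    for name, (t0, t1) in spans.items():
        sel = (t >= t0) & (t < t1)
        truncated = t1 > duration_s
        if truncated:
            log.warning("%s window [%.0f, %.0f) truncated at record end %.0f s",
                        name, t0, t1, duration_s)
        windows[name] = PhaseWindow(label=name, span=(t0, t1), values=v[sel],
                                    truncated=truncated)
    return PhaseWindows(**windows)


def feature_table(cohort, m: int = DEFAULT_M, r_frac: float = DEFAULT_R_FRAC,
                  k_max: int = DEFAULT_K_MAX,
                  r_resolution: float = DEFAULT_R_RESOLUTION) -> pd.DataFrame:
    """Feature rows for subject x wavelength x stressor x phase.

    ``cohort`` is an iterable of ``(subject_id, {channel: AcSeries},
    schedule, duration_s)``. Windows too short for a feature leave that cell
    missing (NaN); the event is logged.
    """
    rows = []
    for subject_id, channel_ac, schedule, duration_s in cohort:
        for channel, ac in channel_ac.items():
            for epoch in schedule.epochs:
                stressor = epoch[0]
                phases = extract_phase_windows(ac, epoch, duration_s)
                for win in phases:
                    if win.n_beats >= 1:
                        feats = compute_features(
                            win.values, m=m, r_frac=r_frac, k_max=k_max,
                            r_resolution=r_resolution).to_dict()
                    else:
                        feats = {}
                        log.warning("empty window %s/%s/%s/%s", subject_id,
                                    channel, stressor, win.label)
                    if feats.get("sampen") is None:
                        log.info("undefined SampEn: %s/%s/%s/%s", subject_id,
                                 channel, stressor, win.label)
                    row = dict(subject=subject_id, wavelength=channel,
                               stressor=stressor, phase=win.label,
                               n_beats=win.n_beats, truncated=win.truncated)
                    for name in ("mean", "sd", "katz", "petrosian", "higuchi",
                                 "sampen", "total_sampen", "avg_sampen", "q"):
                        val = feats.get(name)
                        row[name] = np.nan if val is None else val
                    rows.append(row)
    return pd.DataFrame(rows)
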