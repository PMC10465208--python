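"""Plain-CSV readers and writers for records, schedules and results."""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .fiducials import AcSeries, FiducialSet
from .synthetic import GroundTruth
from .types import CHANNELS, EventSchedule, PpgRecord

FLOAT_FMT = "%.10g"
PPG_COLUMNS = ("time",) + CHANNELS


def read_ppg_csv(path, declared_fs: float | None = None) -> PpgRecord:
    """Read a ``time,green,blue,ir,red`` CSV; the sampling rate is inferred
    from the median time step (a >1% mismatch with ``declared_fs`` warns)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in PPG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    bad = df[list(PPG_COLUMNS)].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]  # 1-based incl. header
        raise ValueError(f"{path.name}: malformed values at file row(s) {rows}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path.name}: need at least 2 samples")
    steps = np.diff(t)
    non_monotone = np.where(steps <= 0)[0]
    if len(non_monotone):
        raise ValueError(f"{path.name}: time not strictly increasing at file row "
                         f"{int(non_monotone[0]) + 3}")
    fs = 1.0 / float(np.median(steps))
    if declared_fs is not None and abs(fs - declared_fs) > 0.01 * declared_fs:
        warnings.warn(f"{path.name}: inferred fs {fs:.3f} Hz differs from "
                      f"declared {declared_fs:.3f} Hz by more than 1%")
    return PpgRecord(fs=fs, data=df[list(PPG_COLUMNS)].astype(float),
                     subject_id=path.stem)


def write_ppg_csv(record: PpgRecord, path) -> None:
    record.data.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_schedule_csv(path) -> EventSchedule:
    return EventSchedule.from_frame(pd.read_csv(path))


def write_schedule_csv(schedule: EventSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def write_ground_truth_csv(truth: GroundTruth, path) -> None:
    k = len(truth.true_peak_times)
    df = pd.DataFrame({
        "peak_time_s": truth.true_peak_times,
        "onset_time_s": np.concatenate([[np.nan], truth.true_onset_times]),
        "ibi_s": np.resize(truth.true_ibi_series, k),
        "ac": np.concatenate([[np.nan], truth.true_ac_series]),
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_fiducials_csv(ac: AcSeries, fiducials: FiducialSet, path) -> None:
    df = pd.DataFrame({
        "beat_time_s": ac.beat_times,
        "peak_idx": fiducials.peak_indices[1:],
        "onset_idx": fiducials.onset_indices,
        "ac": ac.ac_values,
        "kept": ac.kept_mask.astype(int),
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_fiducials_csv(path) -> AcSeries:
    df = pd.read_csv(path)
    return AcSeries(beat_times=df["beat_time_s"].to_numpy(float),
                    ac_values=df["ac"].to_numpy(float),
                    kept_mask=df["kept"].to_numpy(int).astype(bool))


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
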