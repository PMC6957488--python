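"""Reading, writing, epoching and minute-averaging of recordings.

Canonical on-disk form is a long CSV with columns
``subject_id, group, condition, channel, time_s, value`` (UTF-8, '.'
decimal), one row per sample, rows within a channel in nondecreasing time.
An optional reader for MATLAB v5 exports maps workspace variables onto
records via a user-supplied name map; CSV remains canonical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError
from .records import CHANNELS, CONDITIONS, GROUPS, EpochSpec, SignalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_matlab_export",
    "extract_epoch",
    "extract_window",
    "minute_average",
]

_COLUMNS = ["subject_id", "group", "condition", "channel", "time_s", "value"]

# tolerance for comparing sample times to window edges (seconds)
_T_EPS = 1e-9


def write_dataset(records: list[SignalRecord], path) -> None:
    """Write records as the canonical long CSV at full float precision."""
    frames = []
    for rec in records:
        frames.append(pd.DataFrame({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "condition": rec.condition,
            "channel": rec.channel,
            "time_s": rec.times,
            "value": rec.values,
        }))
    df = pd.concat(frames, ignore_index=True)
    # %.17g guarantees exact float round-trip through text
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path, strict: bool = True) -> list[SignalRecord]:
    """Read and validate a long-CSV dataset.

    The sampling rate of each channel is inferred from the median time
    step; a gap larger than 1.5x the median step, a non-monotone time, a
    duplicate (subject, condition, channel, time) row or a non-numeric
    value is a :class:`FormatError` naming the offending row. With
    ``strict=False`` the offending *subject* is skipped with a logged
    warning (one corrupt subject should not sink a cohort) and the rest
    are returned.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str,
                                  "condition": str, "channel": str},
                     float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    # row numbers as in the file (header is row 1)
    df["_row"] = df.index + 2

    records: list[SignalRecord] = []
    bad_subjects: set[str] = set()
    for (subj, cond, chan), g in df.groupby(
            ["subject_id", "condition", "channel"], sort=True):
        try:
            records.append(_build_record(path, subj, cond, chan, g))
        except FormatError as exc:
            if strict:
                raise
            if subj not in bad_subjects:
                logger.warning("skipping subject %r: %s", subj, exc)
                bad_subjects.add(subj)
    if bad_subjects:
        records = [r for r in records if r.subject_id not in bad_subjects]
    return records


def _build_record(path, subj, cond, chan, g: pd.DataFrame) -> SignalRecord:
    times = pd.to_numeric(g["time_s"], errors="coerce").to_numpy()
    values = pd.to_numeric(g["value"], errors="coerce").to_numpy()
    rows = g["_row"].to_numpy()
    for arr, col in ((times, "time_s"), (values, "value")):
        bad = ~np.isfinite(arr)
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric {col} at row {int(rows[bad][0])} "
                f"(subject {subj!r})")
    dt = np.diff(times)
    if (dt < 0).any():
        i = int(np.argmax(dt < 0))
        raise FormatError(
            f"{path}: time decreases at row {int(rows[i + 1])} (subject {subj!r})")
    if (dt == 0).any():
        i = int(np.argmax(dt == 0))
        raise FormatError(
            f"{path}: duplicate (subject, condition, channel, time) at row "
            f"{int(rows[i + 1])}")
    if len(times) < 2:
        raise FormatError(f"{path}: channel {chan!r} of subject {subj!r} has "
                          f"fewer than 2 samples")
    step = float(np.median(dt))
    if (dt > 1.5 * step).any():
        i = int(np.argmax(dt > 1.5 * step))
        raise FormatError(
            f"{path}: sampling gap at row {int(rows[i + 1])} "
            f"({dt[i]:.6g} s vs median step {step:.6g} s)")
    group = str(g["group"].iloc[0])
    if group not in GROUPS or cond not in CONDITIONS or chan not in CHANNELS:
        raise FormatError(
            f"{path}: unknown group/condition/channel "
            f"({group!r}, {cond!r}, {chan!r}) at row {int(rows[0])}")
    return SignalRecord(subject_id=subj, group=group, condition=cond,
                        channel=chan, sampling_rate_hz=1.0 / step,
                        t0_s=float(times[0]), values=values)


def read_matlab_export(path, name_map: dict[str, dict], sampling_rate_hz: float = 3.0,
                       t0_s: float = 0.0) -> list[SignalRecord]:
    """Read a MATLAB v5 export.

    ``name_map`` maps MATLAB variable names to record metadata, e.g.
    ``{"oxy": {"subject_id": "TS01", "group": "TS", "condition": "38",
    "channel": "oxy_sat"}}``. Variables must be numeric vectors.
    """
    from scipy.io import loadmat

    mat = loadmat(path, squeeze_me=True)
    records = []
    for var, meta in name_map.items():
        if var not in mat:
            raise FormatError(f"{path}: variable {var!r} not found")
        values = np.asarray(mat[var], dtype=float).ravel()
        records.append(SignalRecord(sampling_rate_hz=sampling_rate_hz,
                                    t0_s=t0_s, values=values, **meta))
    return records


def extract_window(rec: SignalRecord, start_s: float, end_s: float) -> SignalRecord:
    """Sub-series on the half-open window [start_s, end_s)."""
    if not end_s > start_s:
        raise RangeError("window must have positive length")
    t_last = rec.t0_s + rec.n_samples / rec.sampling_rate_hz
    if start_s < rec.t0_s - _T_EPS or end_s > t_last + _T_EPS:
        raise RangeError(
            f"window [{start_s}, {end_s}) outside recording span "
            f"[{rec.t0_s}, {t_last})")
    fs = rec.sampling_rate_hz
    i0 = int(np.ceil((start_s - rec.t0_s) * fs - _T_EPS))
    i1 = int(np.ceil((end_s - rec.t0_s) * fs - _T_EPS))
    i0 = max(i0, 0)
    i1 = min(i1, rec.n_samples)
    if i1 <= i0:
        raise RangeError("window contains no samples")
    return rec.with_values(rec.values[i0:i1], t0_s=rec.t0_s + i0 / fs)


def extract_epoch(rec: SignalRecord, spec: EpochSpec, which: str) -> SignalRecord:
    """Extract one protocol epoch (baseline, stimulation or post)."""
    start, end = spec.window(which)
    return extract_window(rec, start, end)


def minute_average(rec: SignalRecord, grid_step_s: float = 60.0):
    """Centred one-minute means on a regular grid.

    For each grid time t (multiples of ``grid_step_s`` from recording
    start) the mean of the samples in the half-open window
    [t - 30 s, t + 30 s) is returned; grid points whose window is not
    fully inside the recording are dropped.

    Returns
    -------
    times, means : numpy.ndarray
        Grid times (s) and window means.
    """
    if grid_step_s <= 0:
        raise RangeError("grid_step_s must be positive")
    half = 30.0
    if rec.duration_s < 2 * half:
        raise RangeError("record shorter than one averaging window")
    t_end = rec.t0_s + rec.duration_s
    fs = rec.sampling_rate_hz
    times, means = [], []
    k = 0
    while True:
        t = rec.t0_s + k * grid_step_s
        if t + half > t_end + _T_EPS:
            break
        if t - half >= rec.t0_s - _T_EPS:
            i0 = int(np.ceil((t - half - rec.t0_s) * fs - _T_EPS))
            i1 = int(np.ceil((t + half - rec.t0_s) * fs - _T_EPS))
            times.append(t)
            means.append(float(rec.values[i0:i1].mean()))
        k += 1
    return np.asarray(times), np.asarray(means)
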