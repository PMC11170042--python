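"""Core time-series containers for wearable recordings.

All series share one time convention: timestamps are float seconds since the
session start (a timezone-naive local ``datetime``), and every interval —
gaps, schedule blocks, posture epochs, MSDA windows — is half-open
``[start, end)``.  Gaps are explicit: samples never exist inside a declared
gap, and downstream operations must treat gapped time as missing rather than
as zero activity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

POSTURE_LABELS = ("lying", "sitting_standing", "walking", "gap")
SCHEDULE_LABELS = ("training", "bathing_gap", "device_swap")

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


class SeriesError(ValueError):
    """Malformed or inconsistent series data."""


def _check_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    out = []
    for s, e in intervals:
        s, e = float(s), float(e)
        if e < s:
            raise SeriesError(f"interval end {e} precedes start {s}")
        out.append((s, e))
    return sorted(out)


def _mask_in_intervals(t: np.ndarray, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean mask of timestamps falling inside any half-open interval."""
    mask = np.zeros(t.shape, dtype=bool)
    for s, e in intervals:
        mask |= (t >= s) & (t < e)
    return mask


def seconds_of_day(start: datetime, t: np.ndarray | float):
    """Map session-relative seconds to local clock seconds-of-day [0, 86400)."""
    midnight = start.replace(hour=0, minute=0, second=0, microsecond=0)
    offset = (start - midnight).total_seconds()
    return (np.asarray(t, dtype=float) + offset) % 86400.0


@dataclass
class AccelSeries:
    """Tri-axial acceleration in g, sampled at a nominal rate.

    ``xyz`` is (n, 3); the z column is the device's longitudinal (trunk)
    axis, so gravity lies along +z when the wearer is upright.
    """

    t: np.ndarray
    xyz: np.ndarray
    rate: float
    start: datetime
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise SeriesError("xyz must be (n, 3)")
        if self.t.shape[0] != self.xyz.shape[0]:
            raise SeriesError("timestamp/sample length mismatch")
        if self.rate <= 0:
            raise SeriesError("nominal rate must be positive")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise SeriesError("timestamps must be strictly increasing")
        self.gaps = _check_intervals(self.gaps)
        if self.t.size and _mask_in_intervals(self.t, self.gaps).any():
            raise SeriesError("samples present inside a declared gap")

    @property
    def duration(self) -> float:
        return float(self.t[-1] + 1.0 / self.rate) if self.t.size else 0.0

    @property
    def norm(self) -> np.ndarray:
        """Euclidean norm of each sample (cached; treat as read-only)."""
        cached = getattr(self, "_norm", None)
        if cached is None or cached.shape[0] != self.xyz.shape[0]:
            cached = np.linalg.norm(self.xyz, axis=1)
            object.__setattr__(self, "_norm", cached)
        return cached

    def to_frame(self) -> pd.DataFrame:
        ts = pd.to_datetime(self.start) + pd.to_timedelta(self.t, unit="s")
        return pd.DataFrame(
            {
                "timestamp_iso8601": ts.strftime(_TS_FORMAT),
                "ax_g": self.xyz[:, 0],
                "ay_g": self.xyz[:, 1],
                "az_g": self.xyz[:, 2],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class HeartRateSeries:
    """Heart rate in beats/min, gap-aware, nominally 1 Hz."""

    t: np.ndarray
    hr: np.ndarray
    start: datetime
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.t.shape != self.hr.shape:
            raise SeriesError("timestamp/sample length mismatch")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise SeriesError("timestamps must be strictly increasing")
        if self.hr.size and not np.all(self.hr > 0):
            raise SeriesError("heart rate must be positive everywhere")
        self.gaps = _check_intervals(self.gaps)
        if self.t.size and _mask_in_intervals(self.t, self.gaps).any():
            raise SeriesError("samples present inside a declared gap")

    def to_frame(self) -> pd.DataFrame:
        ts = pd.to_datetime(self.start) + pd.to_timedelta(self.t, unit="s")
        return pd.DataFrame(
            {"timestamp_iso8601": ts.strftime(_TS_FORMAT), "hr_bpm": self.hr}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PeriodSchedule:
    """Therapist-style labeled intervals: training blocks, bathing gaps and
    the device-swap marker (zero-duration).  Whatever wear time is not
    training and not gapped is, by definition, nontraining."""

    intervals: list[tuple[float, float, str]]
    start: datetime
    source: str = ""

    def __post_init__(self) -> None:
        rows = []
        for s, e, lab in self.intervals:
            if lab not in SCHEDULE_LABELS:
                raise SeriesError(f"unknown schedule label {lab!r}")
            if float(e) < float(s):
                raise SeriesError("schedule interval end precedes start")
            rows.append((float(s), float(e), lab))
        rows.sort()
        tr = [(s, e) for s, e, lab in rows if lab == "training"]
        for (s1, e1), (s2, e2) in zip(tr, tr[1:]):
            if s2 < e1:
                raise SeriesError("training intervals overlap")
        self.intervals = rows

    def by_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    @property
    def training(self) -> list[tuple[float, float]]:
        return self.by_label("training")

    @property
    def gap_intervals(self) -> list[tuple[float, float]]:
        """Intervals during which no data exists (bathing plus any nonzero swap)."""
        return [
            (s, e)
            for s, e, lab in self.intervals
            if lab in ("bathing_gap", "device_swap") and e > s
        ]

    def to_frame(self) -> pd.DataFrame:
        base = pd.to_datetime(self.start)
        rows = [
            {
                "start": (base + timedelta(seconds=s)).strftime(_TS_FORMAT),
                "end": (base + timedelta(seconds=e)).strftime(_TS_FORMAT),
                "label": lab,
            }
            for s, e, lab in self.intervals
        ]
        return pd.DataFrame(rows, columns=["start", "end", "label"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PostureSeries:
    """Posture epochs tiling a session: lying / sitting_standing / walking / gap."""

    epochs: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        rows = []
        for s, e, lab in self.epochs:
            if lab not in POSTURE_LABELS:
                raise SeriesError(f"unknown posture label {lab!r}")
            rows.append((float(s), float(e), lab))
        rows.sort()
        for (s1, e1, _), (s2, e2, _) in zip(rows, rows[1:]):
            if not np.isclose(e1, s2):
                raise SeriesError("posture epochs must tile the session")
        self.epochs = rows

    def label_at(self, t: np.ndarray) -> np.ndarray:
        """Posture label for each timestamp (object array of str)."""
        t = np.asarray(t, dtype=float)
        starts = np.array([s for s, _, _ in self.epochs])
        labels = np.array([lab for _, _, lab in self.epochs], dtype=object)
        idx = np.searchsorted(starts, t, side="right") - 1
        idx = np.clip(idx, 0, len(labels) - 1)
        return labels[idx]

    def intervals_for(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.epochs if lab == label]

    def minutes_by_label(self, lo: float | None = None, hi: float | None = None) -> dict[str, float]:
        """Minutes per label, optionally clipped to [lo, hi)."""
        out = {lab: 0.0 for lab in POSTURE_LABELS}
        for s, e, lab in self.epochs:
            if lo is not None:
                s = max(s, lo)
            if hi is not None:
                e = min(e, hi)
            if e > s:
                out[lab] += (e - s) / 60.0
        return out


@dataclass
class MsdaSeries:
    """Per-window moving-SD of acceleration: the activity metric.

    One value per consecutive non-overlapping window of ``window_length``
    seconds; windows overlapping a gap are absent, not zero.
    """

    starts: np.ndarray
    values: np.ndarray
    window_length: float = 2.0

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.starts.shape != self.values.shape:
            raise SeriesError("window start/value length mismatch")
        if self.values.size and np.nanmin(self.values) < 0:
            raise SeriesError("msda must be nonnegative")
        if self.starts.size > 1 and not np.all(np.diff(self.starts) > 0):
            raise SeriesError("windows must be ordered and non-overlapping")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_start": self.starts, "msda_g": self.values})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Readers for the CSV dialects written above
# ---------------------------------------------------------------------------


def _parse_timestamps(col: pd.Series, path: str | Path) -> tuple[datetime, np.ndarray]:
    try:
        ts = pd.to_datetime(col, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SeriesError(f"{path}: unparseable timestamp ({exc})") from exc
    start = ts.iloc[0].to_pydatetime()
    t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    return start, t


def read_accel_csv(
    path: str | Path,
    rate: float,
    gaps: Sequence[tuple[float, float]] = (),
) -> AccelSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["timestamp_iso8601", "ax_g", "ay_g", "az_g"]
    if list(df.columns) != expected:
        raise SeriesError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    start, t = _parse_timestamps(df["timestamp_iso8601"], path)
    xyz = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    if not np.isfinite(xyz).all():
        bad = int(np.argwhere(~np.isfinite(xyz).all(axis=1))[0, 0])
        raise SeriesError(f"{path}: non-numeric acceleration at data row {bad + 1}")
    return AccelSeries(t=t, xyz=xyz, rate=rate, start=start, gaps=list(gaps))


def read_hr_csv(
    path: str | Path, gaps: Sequence[tuple[float, float]] = ()
) -> HeartRateSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["timestamp_iso8601", "hr_bpm"]
    if list(df.columns) != expected:
        raise SeriesError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    start, t = _parse_timestamps(df["timestamp_iso8601"], path)
    hr = df["hr_bpm"].to_numpy(dtype=float)
    if not np.isfinite(hr).all():
        bad = int(np.argwhere(~np.isfinite(hr))[0, 0])
        raise SeriesError(f"{path}: non-numeric heart rate at data row {bad + 1}")
    return HeartRateSeries(t=t, hr=hr, start=start, gaps=list(gaps))


def read_schedule_csv(path: str | Path, session_start: datetime | None = None) -> PeriodSchedule:
    df = pd.read_csv(path)
    expected = ["start", "end", "label"]
    if list(df.columns) != expected:
        raise SeriesError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df.empty:
        if session_start is None:
            raise SeriesError(f"{path}: empty schedule needs an explicit session start")
        return PeriodSchedule(intervals=[], start=session_start)
    try:
        starts = pd.to_datetime(df["start"], format="ISO8601")
        ends = pd.to_datetime(df["end"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SeriesError(f"{path}: unparseable schedule timestamp ({exc})") from exc
    base = session_start or starts.iloc[0].to_pydatetime()
    base_ts = pd.Timestamp(base)
    intervals = [
        (
            (s - base_ts).total_seconds(),
            (e - base_ts).total_seconds(),
            str(lab),
        )
        for s, e, lab in zip(starts, ends, df["label"])
    ]
    return PeriodSchedule(intervals=intervals, start=base)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
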