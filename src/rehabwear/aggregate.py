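"""Calendar-day segmentation and the per-day / per-session summaries.

Days are local calendar days ``[00:00, 24:00)``; partial leading/trailing
slices of a session are flagged and, by default, excluded from cohort
means.  Within a day, MSDA windows belong to the training period when
their *start* lies in a training interval (this keeps the training +
nontraining decomposition exactly additive); %HRR samples are assigned the
same way and period means are unweighted sample means.  Gapped windows and
samples count toward no period.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .series import (
    MsdaSeries,
    PeriodSchedule,
    PostureSeries,
    _mask_in_intervals,
)
from .synthetic import PatientProfile


@dataclass
class DayView:
    """One calendar-day slice of a session, in session-relative seconds."""

    index: int
    date: datetime
    lo: float
    hi: float
    full: bool

    @property
    def minutes(self) -> float:
        return (self.hi - self.lo) / 60.0


def split_days(session_start: datetime, session_seconds: float) -> list[DayView]:
    """Slice ``[0, session_seconds)`` into local calendar days.

    A slice is *full* when it covers the complete 1440 minutes.  Sessions
    shorter than 24 h yield only partial (flagged) slices.
    """
    if session_seconds <= 0:
        raise ValueError("session has no duration")
    midnight = session_start.replace(hour=0, minute=0, second=0, microsecond=0)
    offset = (session_start - midnight).total_seconds()
    views: list[DayView] = []
    day0 = -offset
    d = 0
    while day0 + d * 86400.0 < session_seconds:
        lo = day0 + d * 86400.0
        hi = lo + 86400.0
        clo, chi = max(lo, 0.0), min(hi, session_seconds)
        if chi > clo:
            views.append(
                DayView(
                    index=d,
                    date=midnight + timedelta(days=d),
                    lo=clo,
                    hi=chi,
                    full=bool(np.isclose(chi - clo, 86400.0)),
                )
            )
        d += 1
    return views


@dataclass
class DailySummary:
    """Per patient-day metrics; None marks genuinely missing quantities
    (an empty period or a fully gapped day), never silently zero."""

    patient_id: str
    session: str
    day_index: int
    full_day: bool
    minutes_lying: float
    minutes_sitting_standing: float
    minutes_walking: float
    minutes_gap: float
    msda_total: Optional[float]
    msda_training: Optional[float]
    msda_nontraining: Optional[float]
    hrr_mean_total: Optional[float]
    hrr_mean_training: Optional[float]
    hrr_mean_nontraining: Optional[float]
    hr_rest: float


def aggregate_day(
    msda: MsdaSeries,
    hrr_t: np.ndarray,
    hrr_pct: np.ndarray,
    posture: PostureSeries,
    schedule: PeriodSchedule,
    day: DayView,
    patient_id: str = "",
    session: str = "",
    hr_rest: float = float("nan"),
) -> DailySummary:
    training = schedule.training
    gaps = schedule.gap_intervals

    # --- MSDA sums, additive by construction ---
    in_day = (msda.starts >= day.lo) & (msda.starts < day.hi)
    w_starts = msda.starts[in_day]
    w_vals = msda.values[in_day]
    if w_vals.size == 0:
        ms_tr = ms_nt = ms_tot = None
    else:
        in_train = _mask_in_intervals(w_starts, training)
        ms_tr = float(w_vals[in_train].sum())
        ms_nt = float(w_vals[~in_train].sum())
        ms_tot = ms_tr + ms_nt

    # --- %HRR period means ---
    hsel = (hrr_t >= day.lo) & (hrr_t < day.hi)
    ht, hv = hrr_t[hsel], hrr_pct[hsel]
    if ht.size == 0:
        h_tot = h_tr = h_nt = None
    else:
        tr_mask = _mask_in_intervals(ht, training)
        h_tot = float(hv.mean())
        h_tr = float(hv[tr_mask].mean()) if tr_mask.any() else None
        h_nt = float(hv[~tr_mask].mean()) if (~tr_mask).any() else None

    # --- posture minutes (epochs clipped to the day) ---
    mins = posture.minutes_by_label(lo=day.lo, hi=day.hi)
    # gapped schedule time that produced no epochs at all still counts as gap
    return DailySummary(
        patient_id=patient_id,
        session=session,
        day_index=day.index,
        full_day=day.full,
        minutes_lying=mins["lying"],
        minutes_sitting_standing=mins["sitting_standing"],
        minutes_walking=mins["walking"],
        minutes_gap=mins["gap"],
        msda_total=ms_tot,
        msda_training=ms_tr,
        msda_nontraining=ms_nt,
        hrr_mean_total=h_tot,
        hrr_mean_training=h_tr,
        hrr_mean_nontraining=h_nt,
        hr_rest=hr_rest,
    )


_METRICS = [
    "minutes_lying",
    "minutes_sitting_standing",
    "minutes_walking",
    "minutes_gap",
    "msda_total",
    "msda_training",
    "msda_nontraining",
    "hrr_mean_total",
    "hrr_mean_training",
    "hrr_mean_nontraining",
    "hr_rest",
]


def daily_frame(summaries: list[DailySummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def cohort_summaries(
    summaries: list[DailySummary],
    profiles: list[PatientProfile],
    full_days_only: bool = True,
) -> pd.DataFrame:
    """Session-level cohort table: metrics averaged over each session's
    (by default full) days, one row per patient-session, joined with age,
    sex and the session's FIM motor score.

    Patients with a missing session still get a row of missing markers so
    paired and cross-sectional analyses can account for them explicitly.
    """
    prof = {p.patient_id: p for p in profiles}
    df = daily_frame(summaries)
    if df.empty:
        raise ValueError("no daily summaries to aggregate")
    if full_days_only:
        used = df[df["full_day"]]
    else:
        used = df
    rows = []
    sessions = sorted(df["session"].unique())
    for p in profiles:
        for sess in sessions:
            sel = used[(used["patient_id"] == p.patient_id) & (used["session"] == sess)]
            row: dict = {
                "patient_id": p.patient_id,
                "session": sess,
                "age": p.age,
                "sex": p.sex,
                "fim_motor": p.fim_motor(sess),
                "n_full_days": int(len(sel)),
            }
            for m in _METRICS:
                row[m] = float(sel[m].mean()) if len(sel) and sel[m].notna().any() else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
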