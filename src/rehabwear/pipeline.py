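"""End-to-end processing: raw session streams -> daily summaries -> cohort
table -> statistics, plus the simulation-based recovery harnesses that
validate the whole chain against generator ground truth."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from . import aggregate, signal_metrics, stats
from .series import AccelSeries, HeartRateSeries, PeriodSchedule
from .synthetic import Cohort, PatientProfile, ScenarioConfig, SessionData, generate_cohort


def load_admission_calibration() -> dict:
    """Packaged calibration constants for the admission-phase scenario
    (cohort-mean intensity and activity levels used as generator targets)."""
    with resources.files("rehabwear").joinpath("data/admission_calibration.json").open() as fh:
        return json.load(fh)


@dataclass
class SessionResult:
    posture: "object"
    msda: "object"
    hrr_params: signal_metrics.HrrParams
    hrr_t: np.ndarray
    hrr_pct: np.ndarray
    daily: list[aggregate.DailySummary]


def process_session(
    accel: AccelSeries,
    hr: HeartRateSeries,
    schedule: PeriodSchedule,
    profile: PatientProfile,
    session: str,
    epoch_length: float = 5.0,
    msda_window: float = 2.0,
    hr_max_formula: str = signal_metrics.CLASSIC_220,
    full_days_only: bool = True,
) -> SessionResult:
    """Run the full measurement chain for one patient-session."""
    context = f"{profile.patient_id}/{session}"
    msda = signal_metrics.compute_msda(accel, window_length=msda_window)
    posture = signal_metrics.classify_posture_full(
        accel, epoch_length=epoch_length, msda=msda if msda_window == 2.0 else None
    )
    params = signal_metrics.hrr_params(
        hr, posture, profile, formula=hr_max_formula, context=context
    )
    hrr_t, hrr_pct = signal_metrics.percent_hrr(hr, params)
    days = aggregate.split_days(accel.start, accel.duration)
    daily = [
        aggregate.aggregate_day(
            msda, hrr_t, hrr_pct, posture, schedule, day,
            patient_id=profile.patient_id, session=session, hr_rest=params.hr_rest,
        )
        for day in days
    ]
    return SessionResult(
        posture=posture, msda=msda, hrr_params=params,
        hrr_t=hrr_t, hrr_pct=hrr_pct, daily=daily,
    )


def process_cohort(cohort: Cohort, **kwargs) -> pd.DataFrame:
    """Process every session of a cohort into the cohort table."""
    summaries: list[aggregate.DailySummary] = []
    for (pid, sess), data in sorted(cohort.sessions.items()):
        profile = next(p for p in cohort.profiles if p.patient_id == pid)
        res = process_session(data.accel, data.hr, data.schedule, profile, sess, **kwargs)
        summaries.extend(res.daily)
    return aggregate.cohort_summaries(summaries, cohort.profiles)


# ---------------------------------------------------------------------------
# Recovery harnesses (simulation studies against ground truth)
# ---------------------------------------------------------------------------


def admission_day_config(seed: int, hours: float = 24.0) -> ScenarioConfig:
    """Single-patient single-day scenario calibrated to the admission-phase
    cohort means (total %HRR target and training-period level from the
    packaged calibration)."""
    cal = load_admission_calibration()
    return ScenarioConfig(
        n_patients=1,
        sessions=("0W",),
        session_hours=hours,
        training_minutes_per_day=cal["training_minutes_per_day"],
        hrr_mean_by_period={
            "training": cal["hrr_training_pct"],
            "nontraining": cal["hrr_nontraining_pct"],
        },
        hrr_total_target=cal["hrr_total_pct"],
        rng_seed=seed,
    )


def recover_day_hrr(seed: int, hours: float = 24.0) -> dict[str, float]:
    """Generate one synthetic day at the admission calibration and recover
    the 24-h mean %HRR through the full resting-HR + max-HR + %HRR chain.

    Returns recovered and true values so calibration error can be split
    from pipeline error.
    """
    cfg = admission_day_config(seed, hours=hours)
    cohort = generate_cohort(cfg)
    profile = cohort.profiles[0]
    data = cohort.sessions[(profile.patient_id, "0W")]
    res = process_session(data.accel, data.hr, data.schedule, profile, "0W")
    day0 = next(d for d in res.daily if d.full_day)
    return {
        "recovered_hrr_mean": day0.hrr_mean_total,
        "true_hrr_mean": data.truth.true_mean_hrr(),
        "recovered_hr_rest": res.hrr_params.hr_rest,
        "true_hr_rest": profile.hr_rest_true,
    }


def recover_structure(
    seed: int,
    n_patients: int = 11,
    hours: float = 24.0,
    coupling_fim: float | None = None,
    coupling_age: float | None = None,
) -> dict[str, float]:
    """Simulate a cohort (single 24-h day per patient), run the full
    pipeline, and measure the rank correlations the study design embeds:
    training MSDA vs FIM motor, nontraining MSDA vs age."""
    kwargs = {}
    if coupling_fim is not None:
        kwargs["coupling_fim_to_training_activity"] = coupling_fim
    if coupling_age is not None:
        kwargs["coupling_age_to_nontraining_activity"] = coupling_age
    cfg = ScenarioConfig(
        n_patients=n_patients, sessions=("0W",), session_hours=hours,
        rng_seed=seed, **kwargs,
    )
    cohort = generate_cohort(cfg)
    table = process_cohort(cohort)
    sub = table[table["session"] == "0W"]
    rho_fim = stats.spearman(sub["fim_motor"].to_numpy(), sub["msda_training"].to_numpy())
    rho_age = stats.spearman(sub["age"].to_numpy(), sub["msda_nontraining"].to_numpy())
    return {"rho_training_vs_fim": rho_fim.rho, "rho_nontraining_vs_age": rho_age.rho}
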