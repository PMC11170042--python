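"""Synthetic inpatient cohorts with full ground truth.

Real ward recordings of this kind are never public, so every downstream
stage is exercised against simulated 48-hour sessions whose posture,
schedule, activity level and intensity process are known exactly.

A simulated day follows a fixed ward template (configurable): a night
lying block, daytime sitting/standing with short walking bouts, scheduled
training blocks, one bathing gap, and lights-out lying in the evening.
Acceleration is a posture-dependent gravity vector plus Gaussian activity
noise (plus a cadence sinusoid while walking); heart rate follows

    HR(t) = HR_rest + f(t) * (HR_max - HR_rest)

where f(t) is an AR(1)-perturbed intensity fraction whose mean over each
ground-truth interval equals that interval's true %HRR / 100.  Because
resting heart rate is *defined* downstream as the night lying median, the
lying intervals carry a true %HRR of 0 by default and the daytime
nontraining level is solved so the nontraining period mean matches the
configured target.

Cohort structure: each patient's training-period activity scale increases
with their FIM motor score and their nontraining activity scale decreases
with age, with multiplicative noise so the realized rank correlations are
strong but not degenerate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.signal import lfilter

from .series import AccelSeries, HeartRateSeries, PeriodSchedule

SESSIONS = ("0W", "4W")

DAY_SECONDS = 86400.0
NIGHT_PROTECTED = (0.0, 5 * 3600.0)  # resting-HR window; training may not touch it


def _clock(s: str) -> float:
    """'HH:MM' -> seconds of day."""
    h, m = s.split(":")
    return 3600.0 * int(h) + 60.0 * int(m)


class ScenarioConfig(BaseModel):
    """Everything the generator needs; defaults emulate the study setting
    (11 patients, two 48-h sessions, 25 Hz acceleration, 1 Hz heart rate,
    ~3 h of scheduled training per day)."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = 11
    session_hours: float = 48.0
    sessions: tuple[str, ...] = SESSIONS
    start_clock: str = "00:00"
    start_date: str = "2020-01-06"
    accel_rate: float = 25.0
    hr_rate: float = 1.0

    # ward timetable (seconds-of-day clock strings)
    night_end: str = "06:00"
    lights_out: str = "21:00"
    training_minutes_per_day: float = 180.0
    training_start_times: tuple[str, ...] = ("09:30", "14:00")
    bathing_gap_start: str = "18:00"
    bathing_gap_minutes: float = 30.0
    swap_gap_minutes: float = 0.0
    walking_minutes_per_day: float = 12.0

    # accelerometer regimes (g)
    posture_noise_sd: dict[str, float] = Field(
        default_factory=lambda: {"lying": 0.01, "sitting_standing": 0.03, "walking": 0.10}
    )
    training_activity_sd: float = 0.06
    walking_cadence: float = 2.0
    walking_amplitude: float = 0.25

    # intensity process (%HRR units)
    hrr_mean_by_period: dict[str, float] = Field(
        default_factory=lambda: {"training": 22.13, "nontraining": 9.47}
    )
    hrr_total_target: Optional[float] = None  # overrides the nontraining entry
    hrr_night: float = 0.0
    hrr_noise_sd: float = 0.02  # stationary SD of the AR(1) term, fraction of HRR
    hrr_noise_tau: float = 30.0  # correlation time, seconds

    # cohort couplings (dimensionless slopes on z-scores)
    coupling_fim_to_training_activity: float = 0.45
    coupling_age_to_nontraining_activity: float = 0.45
    activity_multiplier_noise_sd: float = 0.12
    allow_fim_decline: bool = False

    rng_seed: int = 0

    @field_validator("accel_rate", "hr_rate")
    @classmethod
    def _positive_rate(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("sampling rates must be positive")
        return v

    @field_validator("hrr_mean_by_period")
    @classmethod
    def _hrr_range(cls, v: dict[str, float]) -> dict[str, float]:
        for k, x in v.items():
            if not 0.0 <= x <= 100.0:
                raise ValueError(f"hrr_mean_by_period[{k!r}]={x} outside [0, 100]")
        return v

    @model_validator(mode="after")
    def _validate_timetable(self) -> "ScenarioConfig":
        if not 0 < self.training_minutes_per_day < 24 * 60:
            raise ValueError("training_minutes_per_day must lie in (0, 1440)")
        per_block = 60.0 * self.training_minutes_per_day / len(self.training_start_times)
        for s in self.training_start_times:
            lo = _clock(s)
            hi = lo + per_block
            if lo < NIGHT_PROTECTED[1] and hi > NIGHT_PROTECTED[0]:
                raise ValueError(
                    "training block overlaps the 00:00-05:00 night window used "
                    "for resting-HR extraction"
                )
            if lo < _clock(self.night_end) or hi > _clock(self.lights_out):
                raise ValueError("training blocks must fall inside the waking day")
        bg = _clock(self.bathing_gap_start)
        if any(
            bg < _clock(s) + per_block and bg + 60 * self.bathing_gap_minutes > _clock(s)
            for s in self.training_start_times
        ):
            raise ValueError("bathing gap overlaps a training block")
        return self

    @property
    def start(self) -> datetime:
        return datetime.fromisoformat(f"{self.start_date}T{self.start_clock}:00")


@dataclass
class PatientProfile:
    patient_id: str
    age: int
    sex: str
    fim_motor_0w: int
    fim_motor_4w: int
    hr_rest_true: float
    hr_max_measured: Optional[float] = None

    def __post_init__(self) -> None:
        for v in (self.fim_motor_0w, self.fim_motor_4w):
            if not 13 <= v <= 91:
                raise ValueError(f"FIM motor score {v} outside [13, 91]")
        if self.age < 18:
            raise ValueError("age must be >= 18")

    def fim_motor(self, session: str) -> int:
        return self.fim_motor_0w if session == "0W" else self.fim_motor_4w


@dataclass
class GroundTruthAnnotation:
    """Non-overlapping intervals tiling a session, with per-interval truth.

    ``period`` / ``posture`` are 'gap' for gapped intervals, which carry no
    intensity or activity truth (NaN).
    """

    start: np.ndarray  # seconds since session start
    end: np.ndarray
    posture: np.ndarray  # str
    period: np.ndarray  # training / nontraining / gap
    hrr_mean: np.ndarray  # percent, NaN in gaps
    activity_sd: np.ndarray  # g (SD of the norm), NaN in gaps
    hr_rest: float = float("nan")
    hr_max: float = float("nan")

    def intervals_where(self, **conds: str) -> list[tuple[float, float]]:
        mask = np.ones(self.start.shape, dtype=bool)
        for key, val in conds.items():
            mask &= getattr(self, key) == val
        return [(float(s), float(e)) for s, e in zip(self.start[mask], self.end[mask])]

    def duration_where(self, **conds: str) -> float:
        return float(sum(e - s for s, e in self.intervals_where(**conds)))

    def true_mean_hrr(self, period: str | None = None) -> float:
        """Duration-weighted true %HRR mean over non-gap intervals."""
        mask = self.period != "gap"
        if period is not None:
            mask &= self.period == period
        w = (self.end - self.start)[mask]
        return float(np.average(self.hrr_mean[mask], weights=w))

    def to_json(self) -> str:
        rows = [
            {
                "start_s": float(s),
                "end_s": float(e),
                "posture": str(po),
                "period": str(pe),
                "true_hrr_mean_pct": None if np.isnan(h) else float(h),
                "true_activity_sd_g": None if np.isnan(a) else float(a),
            }
            for s, e, po, pe, h, a in zip(
                self.start, self.end, self.posture, self.period, self.hrr_mean, self.activity_sd
            )
        ]
        return json.dumps(
            {"hr_rest_bpm": self.hr_rest, "hr_max_bpm": self.hr_max, "intervals": rows},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthAnnotation":
        obj = json.loads(text)
        rows = obj["intervals"]
        get = lambda k, default: np.array(
            [default if r[k] is None else r[k] for r in rows]
        )
        return cls(
            start=get("start_s", np.nan).astype(float),
            end=get("end_s", np.nan).astype(float),
            posture=np.array([r["posture"] for r in rows], dtype=object),
            period=np.array([r["period"] for r in rows], dtype=object),
            hrr_mean=get("true_hrr_mean_pct", np.nan).astype(float),
            activity_sd=get("true_activity_sd_g", np.nan).astype(float),
            hr_rest=obj["hr_rest_bpm"],
            hr_max=obj["hr_max_bpm"],
        )


@dataclass
class SessionData:
    accel: AccelSeries
    hr: HeartRateSeries
    schedule: PeriodSchedule
    truth: GroundTruthAnnotation


# ---------------------------------------------------------------------------
# Day plan
# ---------------------------------------------------------------------------


def _day_template(cfg: ScenarioConfig) -> list[tuple[float, float, str, str]]:
    """One calendar day as (start_s, end_s, posture, period) tuples.

    Times are seconds of day; walking bouts are carved out of their host
    block; the bathing gap is carved out last.
    """
    night_end = _clock(cfg.night_end)
    lights_out = _clock(cfg.lights_out)
    per_block = 60.0 * cfg.training_minutes_per_day / len(cfg.training_start_times)
    training = [(_clock(s), _clock(s) + per_block) for s in cfg.training_start_times]

    # walking bouts: half inside training (30 min into each block), half in
    # nontraining daytime at fixed clock slots
    n_train_bouts = len(training)
    nt_slots = [_clock("08:00"), _clock("19:30"), _clock("13:00"), _clock("16:45")]
    n_nt_bouts = 2
    bout = 60.0 * cfg.walking_minutes_per_day / (n_train_bouts + n_nt_bouts)
    walks = [(s + 1800.0, s + 1800.0 + bout, "training") for s, _ in training]
    walks += [(s, s + bout, "nontraining") for s in nt_slots[:n_nt_bouts]]

    events: list[tuple[float, float, str, str]] = []
    events.append((0.0, night_end, "lying", "nontraining"))
    events.append((lights_out, DAY_SECONDS, "lying", "nontraining"))
    for s, e in training:
        events.append((s, e, "sitting_standing", "training"))
    for s, e, per in walks:
        events.append((s, e, "walking", per))

    # fill remaining daytime with nontraining sitting/standing
    covered = sorted((s, e) for s, e, _, _ in events)
    cursor = 0.0
    fills = []
    for s, e in covered:
        if s > cursor:
            fills.append((cursor, s, "sitting_standing", "nontraining"))
        cursor = max(cursor, e)
    if cursor < DAY_SECONDS:
        fills.append((cursor, DAY_SECONDS, "sitting_standing", "nontraining"))

    # walking bouts sit inside training/sitting blocks: rebuild as a flat,
    # sorted, non-overlapping tiling by splitting hosts around walks
    tiling: list[tuple[float, float, str, str]] = []
    boundaries = sorted({0.0, DAY_SECONDS} | {x for s, e, _, _ in events + fills for x in (s, e)})
    all_iv = sorted(events + fills, key=lambda r: (r[0], -(r[1] - r[0])))

    def lookup(t: float) -> tuple[str, str]:
        best = None
        for s, e, po, pe in all_iv:
            if s <= t < e:
                # innermost (shortest) interval wins -> walking bouts override hosts
                if best is None or (e - s) < (best[1] - best[0]):
                    best = (s, e, po, pe)
        assert best is not None
        return best[2], best[3]

    for a, b in zip(boundaries, boundaries[1:]):
        po, pe = lookup((a + b) / 2.0)
        tiling.append((a, b, po, pe))

    # carve out the bathing gap
    bg0 = _clock(cfg.bathing_gap_start)
    bg1 = bg0 + 60.0 * cfg.bathing_gap_minutes
    out: list[tuple[float, float, str, str]] = []
    for s, e, po, pe in tiling:
        if e <= bg0 or s >= bg1:
            out.append((s, e, po, pe))
            continue
        if s < bg0:
            out.append((s, bg0, po, pe))
        if e > bg1:
            out.append((bg1, e, po, pe))
    if cfg.bathing_gap_minutes > 0:
        out.append((bg0, bg1, "gap", "gap"))
    out.sort()
    # merge adjacent identical labels
    merged: list[tuple[float, float, str, str]] = []
    for iv in out:
        if merged and merged[-1][2:] == iv[2:] and np.isclose(merged[-1][1], iv[0]):
            merged[-1] = (merged[-1][0], iv[1], iv[2], iv[3])
        else:
            merged.append(iv)
    return merged


def build_session_plan(
    cfg: ScenarioConfig,
) -> list[tuple[float, float, str, str]]:
    """Ground-truth tiling of a whole session in session-relative seconds."""
    day = _day_template(cfg)
    total = cfg.session_hours * 3600.0
    seconds_into_day = (
        cfg.start.hour * 3600.0 + cfg.start.minute * 60.0 + cfg.start.second
    )
    plan: list[tuple[float, float, str, str]] = []
    day0 = -seconds_into_day  # session-relative second at which calendar day 0 began
    n_days = int(np.ceil((total + seconds_into_day) / DAY_SECONDS))
    for d in range(n_days):
        base = day0 + d * DAY_SECONDS
        for s, e, po, pe in day:
            a, b = base + s, base + e
            a, b = max(a, 0.0), min(b, total)
            if b > a:
                plan.append((a, b, po, pe))
    # swap gap at the 24-h mark, if configured as a real gap
    if cfg.swap_gap_minutes > 0 and total > DAY_SECONDS:
        g0, g1 = DAY_SECONDS, DAY_SECONDS + 60.0 * cfg.swap_gap_minutes
        carved = []
        for s, e, po, pe in plan:
            if e <= g0 or s >= g1:
                carved.append((s, e, po, pe))
            else:
                if s < g0:
                    carved.append((s, g0, po, pe))
                if e > g1:
                    carved.append((g1, e, po, pe))
        carved.append((g0, g1, "gap", "gap"))
        plan = sorted(carved)
    return sorted(plan)


# ---------------------------------------------------------------------------
# Cohort structure
# ---------------------------------------------------------------------------


def sample_profiles(cfg: ScenarioConfig, rng: np.random.Generator) -> list[PatientProfile]:
    """Draw a cohort with the study's demographic envelope (age ~65 +/- 13,
    FIM motor ~52 +/- 17, modest 4-week improvement)."""
    profiles = []
    for i in range(cfg.n_patients):
        age = int(np.clip(round(rng.normal(65.0, 13.0)), 40, 90))
        fim0 = int(np.clip(round(rng.normal(52.0, 17.0)), 13, 88))
        gain = round(rng.normal(12.0, 6.0))
        if not cfg.allow_fim_decline:
            gain = max(0, gain)
        fim4 = int(np.clip(fim0 + gain, 13, 91))
        profiles.append(
            PatientProfile(
                patient_id=f"P{i + 1:02d}",
                age=age,
                sex="male" if rng.random() < 0.5 else "female",
                fim_motor_0w=fim0,
                fim_motor_4w=fim4,
                hr_rest_true=float(np.clip(rng.normal(65.0, 8.0), 50.0, 85.0)),
            )
        )
    return profiles


def inject_cohort_structure(
    profiles: list[PatientProfile], cfg: ScenarioConfig, rng: np.random.Generator
) -> dict[tuple[str, str], dict[str, float]]:
    """Per patient-session activity multipliers.

    Training multiplier increases with the session's FIM motor z-score;
    nontraining multiplier decreases with the age z-score; both carry
    multiplicative Gaussian noise.  Zero slopes give multipliers independent
    of FIM and age.
    """
    ages = np.array([p.age for p in profiles], dtype=float)
    z_age = (ages - ages.mean()) / (ages.std() or 1.0)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for session in cfg.sessions:
        fim = np.array([p.fim_motor(session) for p in profiles], dtype=float)
        z_fim = (fim - fim.mean()) / (fim.std() or 1.0)
        for i, p in enumerate(profiles):
            eps_t = rng.normal(0.0, cfg.activity_multiplier_noise_sd)
            eps_n = rng.normal(0.0, cfg.activity_multiplier_noise_sd)
            out[(p.patient_id, session)] = {
                "training": float(
                    max(0.2, 1.0 + cfg.coupling_fim_to_training_activity * z_fim[i] + eps_t)
                ),
                "nontraining": float(
                    max(0.2, 1.0 - cfg.coupling_age_to_nontraining_activity * z_age[i] + eps_n)
                ),
            }
    return out


# ---------------------------------------------------------------------------
# Per-session signal synthesis
# ---------------------------------------------------------------------------

_GRAVITY = {
    # unit gravity direction in device frame: z is the longitudinal axis
    "lying": np.array([1.0, 0.0, 0.0]),
    "sitting_standing": np.array([0.0, 0.0, 1.0]),
    "walking": np.array([0.0, 0.0, 1.0]),
}


def _solve_day_hrr(cfg: ScenarioConfig, plan) -> float:
    """Daytime nontraining %HRR level hitting the configured period target.

    Lying intervals are pinned at ``hrr_night``; if ``hrr_total_target`` is
    set, the *overall* (all non-gap) mean is matched instead of the
    nontraining period mean.
    """
    d_train = sum(e - s for s, e, po, pe in plan if pe == "training")
    d_lying = sum(e - s for s, e, po, pe in plan if pe == "nontraining" and po == "lying")
    d_day_nt = sum(e - s for s, e, po, pe in plan if pe == "nontraining" and po != "lying")
    if d_day_nt == 0:
        return cfg.hrr_night
    h_train = cfg.hrr_mean_by_period["training"]
    if cfg.hrr_total_target is not None:
        total = d_train + d_lying + d_day_nt
        level = (
            cfg.hrr_total_target * total - h_train * d_train - cfg.hrr_night * d_lying
        ) / d_day_nt
    else:
        h_nt = cfg.hrr_mean_by_period["nontraining"]
        level = (h_nt * (d_lying + d_day_nt) - cfg.hrr_night * d_lying) / d_day_nt
    return float(np.clip(level, 0.0, 100.0))


def synthesize_session(
    cfg: ScenarioConfig,
    profile: PatientProfile,
    session: str,
    multipliers: dict[str, float],
    rng: np.random.Generator,
) -> SessionData:
    total = cfg.session_hours * 3600.0
    plan = build_session_plan(cfg)
    hrr_day = _solve_day_hrr(cfg, plan)
    hr_max = profile.hr_max_measured if profile.hr_max_measured else 220.0 - profile.age
    hr_rest = profile.hr_rest_true

    # per-interval truth
    starts = np.array([s for s, _, _, _ in plan])
    ends = np.array([e for _, e, _, _ in plan])
    postures = np.array([po for _, _, po, _ in plan], dtype=object)
    periods = np.array([pe for _, _, _, pe in plan], dtype=object)
    hrr_true = np.full(len(plan), np.nan)
    sd_true = np.full(len(plan), np.nan)
    for k, (po, pe) in enumerate(zip(postures, periods)):
        if pe == "gap":
            continue
        if pe == "training":
            hrr_true[k] = cfg.hrr_mean_by_period["training"]
            sigma = cfg.training_activity_sd * multipliers["training"]
            if po == "walking":
                sigma = cfg.posture_noise_sd["walking"] * multipliers["training"]
        else:
            hrr_true[k] = cfg.hrr_night if po == "lying" else hrr_day
            if po == "lying":
                sigma = cfg.posture_noise_sd["lying"]
            else:
                sigma = cfg.posture_noise_sd[po] * multipliers["nontraining"]
        if po == "walking":
            sd_true[k] = np.sqrt(sigma**2 + cfg.walking_amplitude**2 / 2.0)
        else:
            sd_true[k] = sigma

    truth = GroundTruthAnnotation(
        start=starts, end=ends, posture=postures, period=periods,
        hrr_mean=hrr_true, activity_sd=sd_true, hr_rest=hr_rest, hr_max=float(hr_max),
    )

    gaps = truth.intervals_where(period="gap")

    # ---------------- acceleration ----------------
    n_acc = int(round(total * cfg.accel_rate))
    t_acc = np.arange(n_acc) / cfg.accel_rate
    idx = np.searchsorted(starts, t_acc, side="right") - 1
    keep = (periods[idx] != "gap").astype(bool)

    # per-interval Gaussian sigma (walking truth includes the sinusoid power)
    sigma_iv = np.where(
        postures == "walking",
        np.sqrt(np.maximum(sd_true**2 - cfg.walking_amplitude**2 / 2.0, 0.0)),
        sd_true,
    )
    sigma_iv = np.nan_to_num(sigma_iv, nan=0.0)
    grav_iv = np.zeros((len(plan), 3))
    for k, po in enumerate(postures):
        if po in _GRAVITY:
            grav_iv[k] = _GRAVITY[po]
    xyz = grav_iv[idx] + sigma_iv[idx, None] * rng.normal(size=(n_acc, 3))
    walking = (postures[idx] == "walking").astype(float)
    xyz[:, 2] += (cfg.walking_amplitude * walking) * np.sin(
        2.0 * np.pi * cfg.walking_cadence * t_acc
    )
    np.clip(xyz, -4.0, 4.0, out=xyz)  # keeps the norm well inside the 8 g range
    accel = AccelSeries(
        t=t_acc[keep], xyz=xyz[keep], rate=cfg.accel_rate, start=cfg.start, gaps=gaps
    )

    # ---------------- heart rate ----------------
    n_hr = int(round(total * cfg.hr_rate))
    t_hr = np.arange(n_hr) / cfg.hr_rate
    phi = np.exp(-1.0 / (cfg.hrr_noise_tau * cfg.hr_rate))
    innov_sd = cfg.hrr_noise_sd * np.sqrt(1.0 - phi**2)
    u = lfilter([1.0], [1.0, -phi], rng.normal(0.0, innov_sd, size=n_hr))
    idx_hr = np.searchsorted(starts, t_hr, side="right") - 1
    mu = hrr_true[idx_hr] / 100.0
    keep_hr = periods[idx_hr] != "gap"
    f = np.clip(np.where(np.isnan(mu), 0.0, mu) + u, -0.15, 1.05)
    hr = np.clip(hr_rest + f * (hr_max - hr_rest), 30.0, 220.0)
    hrs = HeartRateSeries(
        t=t_hr[keep_hr], hr=hr[keep_hr], start=cfg.start, gaps=gaps
    )

    # ---------------- schedule ----------------
    sched: list[tuple[float, float, str]] = []
    # merge contiguous training truth intervals (walking bouts split them)
    for s, e in _merge(truth.intervals_where(period="training")):
        sched.append((s, e, "training"))
    for s, e in gaps:
        is_swap = cfg.swap_gap_minutes > 0 and np.isclose(s, DAY_SECONDS)
        sched.append((s, e, "device_swap" if is_swap else "bathing_gap"))
    if total > DAY_SECONDS and cfg.swap_gap_minutes == 0:
        sched.append((DAY_SECONDS, DAY_SECONDS, "device_swap"))
    schedule = PeriodSchedule(intervals=sched, start=cfg.start, source="synthetic ward timetable")

    return SessionData(accel=accel, hr=hrs, schedule=schedule, truth=truth)


def _merge(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[list[float]] = []
    for s, e in sorted(intervals):
        if out and np.isclose(out[-1][1], s):
            out[-1][1] = e
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# Cohort driver
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    config: ScenarioConfig
    profiles: list[PatientProfile]
    sessions: dict[tuple[str, str], SessionData] = field(default_factory=dict)


def generate_cohort(cfg: ScenarioConfig) -> Cohort:
    """Deterministic cohort: identical config (incl. seed) gives bit-identical
    output.  Randomness flows from the config seed through named substreams,
    one per patient-session, so adding patients never perturbs earlier ones."""
    root = np.random.SeedSequence(cfg.rng_seed)
    profile_rng = np.random.Generator(np.random.PCG64(root.spawn(1)[0]))
    profiles = sample_profiles(cfg, profile_rng)
    structure_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([cfg.rng_seed, 999_983]))
    )
    mults = inject_cohort_structure(profiles, cfg, structure_rng)

    cohort = Cohort(config=cfg, profiles=profiles)
    for i, p in enumerate(profiles):
        for j, session in enumerate(cfg.sessions):
            ss = np.random.SeedSequence([cfg.rng_seed, i, j])
            rng = np.random.Generator(np.random.PCG64(ss))
            cohort.sessions[(p.patient_id, session)] = synthesize_session(
                cfg, p, session, mults[(p.patient_id, session)], rng
            )
    return cohort
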