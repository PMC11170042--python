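"""Measurement-level metrics from raw chest-strap streams.

* posture from the gravity direction relative to the trunk axis
  (supine vs upright, upright refined to walking by a cadence test),
* MSDA — the moving standard deviation of acceleration over 2-s windows,
  the step-count-free activity metric,
* resting heart rate — the night lying median,
* maximum heart rate — measured or the age-predicted 220 - age,
* %HRR — percent heart rate reserve, the intensity metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .series import (
    AccelSeries,
    HeartRateSeries,
    MsdaSeries,
    PostureSeries,
    _mask_in_intervals,
    seconds_of_day,
)
from .synthetic import PatientProfile  # the cohort's metadata record

TANAKA = "tanaka"
CLASSIC_220 = "220_minus_age"


class InsufficientNightDataError(RuntimeError):
    """Not enough lying heart-rate samples in the night window to anchor
    the resting heart rate; the caller must not silently fall back."""


class HrrDefinitionError(ValueError):
    """hr_max <= hr_rest: the heart-rate reserve is empty or inverted."""


@dataclass
class HrrParams:
    """Anchors of the heart-rate-reserve transform."""

    hr_rest: float
    hr_max: float
    source_max: str  # "measured" or "age_estimated"

    def __post_init__(self) -> None:
        if not self.hr_rest > 0:
            raise HrrDefinitionError(f"hr_rest={self.hr_rest} must be positive")
        if self.hr_max <= self.hr_rest:
            raise HrrDefinitionError(
                f"hr_max={self.hr_max} must exceed hr_rest={self.hr_rest}"
            )


# ---------------------------------------------------------------------------
# MSDA
# ---------------------------------------------------------------------------


def compute_msda(accel: AccelSeries, window_length: float = 2.0) -> MsdaSeries:
    """Moving SD of the acceleration norm over consecutive windows.

    Windows are ``[k*w, (k+1)*w)`` aligned to the session start; the value
    is the sample SD (denominator n-1) of the Euclidean norm of the samples
    in the window.  Windows that intersect a declared gap, or hold fewer
    than 2 samples, are dropped.  The norm makes the metric invariant to
    strap orientation, and subtracting the window mean removes gravity.
    """
    if window_length * accel.rate < 2:
        raise ValueError("window must span at least 2 samples at the nominal rate")
    if accel.t.size == 0:
        return MsdaSeries(starts=np.array([]), values=np.array([]), window_length=window_length)
    norm = accel.norm
    win = np.floor(accel.t / window_length).astype(np.int64)
    n_win = int(win[-1]) + 1
    counts = np.bincount(win, minlength=n_win)
    sums = np.bincount(win, weights=norm, minlength=n_win)
    sqsums = np.bincount(win, weights=norm * norm, minlength=n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sqsums - sums * sums / np.maximum(counts, 1)) / (counts - 1)
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    starts = np.arange(n_win) * float(window_length)
    ok = counts >= 2
    # a window touching any gap is dropped even if it still has samples
    for gs, ge in accel.gaps:
        k0 = int(np.floor(gs / window_length))
        k1 = int(np.ceil(ge / window_length))
        if ge > gs:
            ok[max(k0, 0) : min(k1, n_win)] = False
    return MsdaSeries(starts=starts[ok], values=sd[ok], window_length=window_length)


# ---------------------------------------------------------------------------
# Posture
# ---------------------------------------------------------------------------


def classify_posture(
    accel: AccelSeries,
    epoch_length: float = 5.0,
    supine_threshold_deg: float = 50.0,
    min_valid_fraction: float = 0.5,
    gravity_kernel_s: float = 2.0,
) -> PostureSeries:
    """Epoch posture labels from the gravity direction.

    Per epoch the gravity vector is estimated as the per-axis median of a
    2-s moving-median-smoothed signal (a robust low-pass); the epoch is
    *lying* when the angle between that vector and the device longitudinal
    axis (z) exceeds the supine threshold, else upright
    (``sitting_standing``; refined to walking separately).  Epochs with
    fewer than ``min_valid_fraction`` of their nominal samples are labeled
    ``gap``.
    """
    duration = accel.duration if accel.t.size else 0.0
    if duration == 0.0:
        return PostureSeries(epochs=[])
    n_ep = int(np.ceil(duration / epoch_length))
    nominal = epoch_length * accel.rate

    ep_idx_full = np.floor(accel.t / epoch_length).astype(np.int64)
    counts = np.bincount(ep_idx_full, minlength=n_ep)

    # gravity is slow: estimate the per-epoch median from a decimated
    # subset of samples (every ``gravity_decimate``-th), which is ample at
    # 25 Hz and keeps long sessions fast
    gravity_decimate = max(1, int(round(accel.rate * epoch_length / 25.0)))
    sub = slice(None, None, gravity_decimate)
    ep_idx = ep_idx_full[sub]

    # per-epoch median per axis; the separate 2-s kernel median is folded in
    # by using the epoch median directly when the epoch is >= the kernel
    med = np.full((n_ep, 3), np.nan)
    order = np.argsort(ep_idx, kind="stable")
    sorted_idx = ep_idx[order]
    boundaries = np.searchsorted(sorted_idx, np.arange(n_ep + 1))
    xyz_sorted = accel.xyz[sub][order]
    sizes = np.diff(boundaries)
    # vectorize the per-epoch median by batching epochs of equal sample count
    for c in np.unique(sizes):
        if c == 0:
            continue
        which = np.flatnonzero(sizes == c)
        rows = (boundaries[which][:, None] + np.arange(c)[None, :]).ravel()
        block = xyz_sorted[rows].reshape(len(which), int(c), 3)
        med[which] = np.median(block, axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        gmag = np.linalg.norm(med, axis=1)
        cosang = np.abs(med[:, 2]) / np.where(gmag > 0, gmag, np.nan)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    labels = np.where(angle > supine_threshold_deg, "lying", "sitting_standing")
    labels = labels.astype(object)
    invalid = (counts < min_valid_fraction * nominal) | ~np.isfinite(angle)
    labels[invalid] = "gap"

    epochs = [
        (k * epoch_length, min((k + 1) * epoch_length, duration), str(labels[k]))
        for k in range(n_ep)
    ]
    return PostureSeries(epochs=_merge_epochs(epochs))


def _merge_epochs(epochs: list[tuple[float, float, str]]) -> list[tuple[float, float, str]]:
    merged: list[tuple[float, float, str]] = []
    for s, e, lab in epochs:
        if merged and merged[-1][2] == lab and abs(merged[-1][1] - s) < 1e-9:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return merged


def detect_walking(
    accel: AccelSeries,
    posture: PostureSeries,
    epoch_length: float = 5.0,
    activity_threshold_g: float = 0.05,
    cadence_band_hz: tuple[float, float] = (1.0, 3.0),
    peak_power_fraction: float = 0.2,
    msda: Optional[MsdaSeries] = None,
) -> PostureSeries:
    """Refine upright epochs to walking.

    An upright epoch becomes *walking* when (a) its mean MSDA reaches the
    activity threshold and (b) the dominant spectral peak of the
    mean-removed norm lies in the cadence band and carries at least
    ``peak_power_fraction`` of the epoch's AC power.  The concentration
    requirement keeps broadband fidgeting (whose argmax bin is arbitrary)
    out of the walking class.
    """
    if accel.t.size == 0 or not posture.epochs:
        return posture
    if msda is None:
        msda = compute_msda(accel)
    norm = accel.norm
    lo, hi = cadence_band_hz

    duration = posture.epochs[-1][1]
    n_ep = int(np.ceil(duration / epoch_length))
    ep_starts = np.arange(n_ep) * epoch_length
    ep_ends = np.minimum(ep_starts + epoch_length, duration)
    labels = posture.label_at(ep_starts + 0.5 * np.diff(np.append(ep_starts, duration)))

    # mean MSDA per epoch (windows assigned by their start time)
    mean_msda = np.zeros(n_ep)
    if msda.starts.size:
        widx = np.floor(msda.starts / epoch_length).astype(np.int64)
        widx = np.clip(widx, 0, n_ep - 1)
        wsum = np.bincount(widx, weights=msda.values, minlength=n_ep)
        wcnt = np.bincount(widx, minlength=n_ep)
        np.divide(wsum, wcnt, out=mean_msda, where=wcnt > 0)

    candidates = np.flatnonzero(
        (labels == "sitting_standing") & (mean_msda >= activity_threshold_g)
    )
    i0 = np.searchsorted(accel.t, ep_starts[candidates], side="left")
    i1 = np.searchsorted(accel.t, ep_ends[candidates], side="left")
    for k, a, b in zip(candidates, i0, i1):
        seg = norm[a:b]
        if seg.size < 4:
            continue
        seg = seg - seg.mean()
        spec = np.abs(np.fft.rfft(seg)) ** 2
        spec[0] = 0.0
        total = spec.sum()
        if total <= 0:
            continue
        j = int(np.argmax(spec))
        freq = j * accel.rate / seg.size
        if lo <= freq <= hi and spec[j] >= peak_power_fraction * total:
            labels[k] = "walking"

    epochs = [
        (float(s), float(e), str(lab)) for s, e, lab in zip(ep_starts, ep_ends, labels)
    ]
    return PostureSeries(epochs=_merge_epochs(epochs))


def classify_posture_full(
    accel: AccelSeries,
    epoch_length: float = 5.0,
    msda: Optional[MsdaSeries] = None,
    **kwargs,
) -> PostureSeries:
    """Posture classification including the walking refinement."""
    detect_kwargs = {
        k: kwargs.pop(k)
        for k in ("activity_threshold_g", "cadence_band_hz", "peak_power_fraction")
        if k in kwargs
    }
    base = classify_posture(accel, epoch_length=epoch_length, **kwargs)
    return detect_walking(accel, base, epoch_length=epoch_length, msda=msda, **detect_kwargs)


# ---------------------------------------------------------------------------
# Heart rate anchors and %HRR
# ---------------------------------------------------------------------------


def resting_hr(
    hr: HeartRateSeries,
    posture: PostureSeries,
    night_window: tuple[float, float] = (0.0, 5 * 3600.0),
    min_minutes: float = 30.0,
    context: str = "",
) -> float:
    """Median heart rate while lying between 00:00 and 05:00 local time.

    Samples must be simultaneously inside the clock window and inside a
    lying-labeled epoch; both nights of a 48-h session are pooled into a
    single anchor.  Fails loudly when fewer than ``min_minutes`` of such
    samples exist.
    """
    sod = seconds_of_day(hr.start, hr.t)
    lo, hi = night_window
    in_night = (sod >= lo) & (sod < hi) if lo <= hi else (sod >= lo) | (sod < hi)
    lying = posture.label_at(hr.t) == "lying"
    sel = in_night & lying
    n = int(sel.sum())
    # sample spacing from the median diff; the series is nominally uniform
    dt = float(np.median(np.diff(hr.t))) if hr.t.size > 1 else 1.0
    if n * dt < min_minutes * 60.0:
        raise InsufficientNightDataError(
            f"only {n * dt / 60.0:.1f} min of lying night heart rate "
            f"(< {min_minutes} min required)" + (f" [{context}]" if context else "")
        )
    return float(np.median(hr.hr[sel]))


def max_hr(profile: PatientProfile, formula: str = CLASSIC_220) -> tuple[float, str]:
    """Maximum heart rate: measured when available, else age-predicted.

    The default age formula is 220 - age; the Tanaka alternative
    (208 - 0.7 * age) is available by configuration.
    """
    if profile.hr_max_measured is not None:
        return float(profile.hr_max_measured), "measured"
    if formula == TANAKA:
        return 208.0 - 0.7 * profile.age, "age_estimated"
    return 220.0 - float(profile.age), "age_estimated"


def hrr_params(
    hr: HeartRateSeries,
    posture: PostureSeries,
    profile: PatientProfile,
    formula: str = CLASSIC_220,
    context: str = "",
) -> HrrParams:
    rest = resting_hr(hr, posture, context=context)
    hmax, source = max_hr(profile, formula=formula)
    if hmax <= rest:
        raise HrrDefinitionError(
            f"hr_max={hmax:.1f} <= hr_rest={rest:.1f}"
            + (f" [{context}]" if context else "")
        )
    return HrrParams(hr_rest=rest, hr_max=hmax, source_max=source)


def percent_hrr(hr: HeartRateSeries, params: HrrParams) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise %HRR = 100 * (HR - HR_rest) / (HR_max - HR_rest).

    Returns (timestamps, percent).  Sub-resting values stay negative and
    values may exceed 100; gaps propagate (no samples exist there).
    """
    span = params.hr_max - params.hr_rest
    return hr.t.copy(), 100.0 * (hr.hr - params.hr_rest) / span


def hr_from_percent(pct: np.ndarray, params: HrrParams) -> np.ndarray:
    """Inverse of :func:`percent_hrr` (exact up to floating point)."""
    return params.hr_rest + np.asarray(pct) / 100.0 * (params.hr_max - params.hr_rest)
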