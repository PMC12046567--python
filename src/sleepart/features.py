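"""The nine ART sleep-health features: amount, regularity, timing.

Parametric rest-activity-rhythm features come from the sigmoidally
transformed ("extended") cosine model

    y(t) = min + amp * F(cos(2*pi*(t - phi)/24)),   F(c) = expit(beta*(c - alpha)),

whose parameters are the minimum count level, amplitude, acrophase ``phi``
(clock time of peak activity), width ``alpha`` in [-1, 1] (higher = more of
the day spent near the trough, i.e. at rest) and steepness ``beta`` > 0.
Nonparametric features are interdaily stability (IS) and intradaily
variability (IV) on hourly-binned counts.  Actigraphy sleep features
summarise detected rest intervals (length, circular midpoint, log-SD of the
midpoint), and self-report features are nightly sleep duration and the
bed-to-wake midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .containers import EpochSeries, SleepInterval

#: Offset added to the midpoint SD (hours) before the log transform, so a
#: perfectly regular session (SD = 0) maps to a finite value.  1/120 h = 30 s.
LOG_SD_EPSILON = 1.0 / 120.0
MIN_SLEEP_INTERVALS = 5
BETA_BOUNDS = (1e-2, 50.0)


def extended_cosine_curve(
    t_h: np.ndarray,
    minimum: float,
    amplitude: float,
    acrophase: float,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Mean activity at clock time ``t_h`` under the extended cosine model."""
    c = np.cos(2.0 * np.pi * (np.asarray(t_h, dtype=float) - acrophase) / 24.0)
    return minimum + amplitude * expit(beta * (c - alpha))


@dataclass(frozen=True)
class ExtendedCosineFit:
    """Result of fitting the extended cosine model to one session."""

    minimum: float | None
    amplitude: float | None
    acrophase: float | None  # clock hours in [0, 24)
    alpha: float | None
    beta: float | None
    status: str  # "full" | "partial" | "failed"
    rss: float | None

    @property
    def usable(self) -> bool:
        """At least partial convergence is required to use the parameters."""
        return self.status in ("full", "partial")


_FAILED_FIT = ExtendedCosineFit(None, None, None, None, None, "failed", None)


def fit_extended_cosine(
    series: EpochSeries,
    phi_starts: Sequence[float] = (0.0, 6.0, 12.0, 18.0),
    xtol: float = 1e-12,
) -> ExtendedCosineFit:
    """Fit the extended cosine model by bounded nonlinear least squares.

    Only unmasked epochs enter the fit.  The acrophase is multi-started at
    ``phi_starts`` plus the empirical hour of maximal mean count; the best
    converged solution wins.  Status is ``full`` when the optimiser converged
    with all of alpha/beta interior, ``partial`` when it converged with alpha
    or beta pinned at a bound, and ``failed`` for degenerate input (constant
    or near-constant counts) or non-convergence — failed fits carry no
    usable parameters.
    """
    y = series.counts[~series.excluded]
    t = series.clock_hours()[~series.excluded]
    if len(y) < 48 or np.ptp(y) < 1e-9 or np.std(y) < 1e-9:
        return _FAILED_FIT

    lo5, hi95 = np.percentile(y, [5.0, 95.0])
    amp0 = max(hi95 - lo5, 1e-3)
    # empirical peak hour as an extra acrophase start
    hour_idx = np.floor(t).astype(int) % 24
    hour_means = np.full(24, np.nan)
    for h in range(24):
        sel = hour_idx == h
        if sel.any():
            hour_means[h] = y[sel].mean()
    starts = list(phi_starts)
    if np.isfinite(hour_means).any():
        starts.append(float(np.nanargmax(hour_means)) + 0.5)

    bounds = (
        np.array([0.0, 1e-6, -12.0, -1.0, BETA_BOUNDS[0]]),
        np.array([np.inf, np.inf, 36.0, 1.0, BETA_BOUNDS[1]]),
    )

    def resid(p: np.ndarray) -> np.ndarray:
        return extended_cosine_curve(t, *p) - y

    best = None
    for phi0 in starts:
        p0 = np.array([max(lo5, 0.0), amp0, phi0, 0.0, 2.0])
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            res = least_squares(
                resid, p0, bounds=bounds, method="trf",
                xtol=xtol, ftol=xtol, gtol=xtol,
            )
        except Exception:  # pragma: no cover - optimiser failure is rare
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return _FAILED_FIT

    minimum, amplitude, phi, alpha, beta = best.x
    if amplitude < 1e-6 or amplitude < 1e-4 * max(np.std(y), 1.0):
        return _FAILED_FIT  # phase unidentifiable without a rhythm
    at_bound = (
        beta >= BETA_BOUNDS[1] * (1 - 1e-6)
        or beta <= BETA_BOUNDS[0] * (1 + 1e-6)
        or abs(alpha) >= 1.0 - 1e-9
    )
    return ExtendedCosineFit(
        minimum=float(minimum),
        amplitude=float(amplitude),
        acrophase=float(phi % 24.0),
        alpha=float(alpha),
        beta=float(beta),
        status="partial" if at_bound else "full",
        rss=float(2.0 * best.cost),
    )


def hourly_means(series: EpochSeries, min_epoch_frac: float = 0.5) -> np.ndarray:
    """Hourly mean counts from unmasked epochs, trimmed to whole 24 h days.

    Hours with fewer than ``min_epoch_frac`` of their epochs unmasked are
    treated as missing and imputed with that hour-of-day's mean across the
    other days (falling back to the overall mean), keeping the sequence
    contiguous as IS/IV require.  A partial trailing day is dropped so the
    length is a multiple of 24.
    """
    per_hour = int(round(3600 / series.epoch_s))
    n = (len(series) // per_hour) * per_hour
    counts = series.counts[:n].reshape(-1, per_hour)
    good = (~series.excluded[:n]).reshape(-1, per_hour)
    with np.errstate(invalid="ignore"):
        means = np.where(
            good.sum(axis=1) >= min_epoch_frac * per_hour,
            np.divide(
                (counts * good).sum(axis=1),
                good.sum(axis=1),
                out=np.zeros(n // per_hour),
                where=good.sum(axis=1) > 0,
            ),
            np.nan,
        )
    n_hours = (len(means) // 24) * 24
    means = means[:n_hours]
    if n_hours and np.isnan(means).any():
        byday = means.reshape(-1, 24)
        hod_mean = np.nanmean(byday, axis=0)
        fill = np.where(np.isfinite(hod_mean), hod_mean, np.nanmean(means))
        means = np.where(np.isnan(means), np.tile(fill, n_hours // 24), means)
    return means


def interdaily_stability(hourly: Sequence[float]) -> float | None:
    """Interdaily stability of an hourly count series.

    IS = N * sum_h (xbar_h - xbar)^2 / (24 * sum_i (x_i - xbar)^2) over the 24
    hour-of-day means ``xbar_h``; ranges from 0 (no stable 24 h pattern) to 1
    (identical days).  Requires >= 48 hourly values, length a multiple of 24,
    and a non-constant series (otherwise ``None`` with a warning).
    """
    x = np.asarray(hourly, dtype=float)
    n = len(x)
    if n < 48 or n % 24 != 0:
        raise ValueError("IS requires >= 48 hourly values in whole days")
    total = np.sum((x - x.mean()) ** 2)
    if total < 1e-300:
        warnings.warn("constant series: IS undefined", stacklevel=2)
        return None
    hod = x.reshape(-1, 24).mean(axis=0)
    return float(n * np.sum((hod - x.mean()) ** 2) / (24.0 * total))


class IVResult(NamedTuple):
    value: float
    out_of_range: bool  # nominal range is [0, 2]


def intradaily_variability(hourly: Sequence[float]) -> IVResult | None:
    """Intradaily variability of an hourly count series.

    IV = N * sum_{i>=2} (x_i - x_{i-1})^2 / ((N-1) * sum_i (x_i - xbar)^2):
    the normalised mean-square successive difference.  Values above the
    nominal [0, 2] range (possible, e.g. for hour-to-hour alternation) are
    returned with ``out_of_range=True``.  Constant series -> ``None``.
    """
    x = np.asarray(hourly, dtype=float)
    n = len(x)
    if n < 48:
        raise ValueError("IV requires >= 48 hourly values")
    total = np.sum((x - x.mean()) ** 2)
    if total < 1e-300:
        warnings.warn("constant series: IV undefined", stacklevel=2)
        return None
    iv = float(n * np.sum(np.diff(x) ** 2) / ((n - 1) * total))
    return IVResult(iv, not (0.0 <= iv <= 2.0))


def circular_mean_h(hours: np.ndarray) -> float:
    """Circular mean of clock times (hours), in [0, 24)."""
    ang = np.asarray(hours, dtype=float) * (2.0 * np.pi / 24.0)
    mean = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float((mean * 24.0 / (2.0 * np.pi)) % 24.0)


class RestSummaries(NamedTuple):
    mean_length_h: float | None
    midpoint_h: float | None
    log_midpoint_sd: float | None


def rest_interval_summaries(
    intervals: Sequence[SleepInterval],
    min_intervals: int = MIN_SLEEP_INTERVALS,
    log_eps: float = LOG_SD_EPSILON,
) -> RestSummaries:
    """Actigraphy-sleep features: mean length, circular mean midpoint, log-SD.

    Midpoints are unwrapped to (-12, 12] h around their circular mean before
    the sample SD, and the SD is reported as ln(SD + ``log_eps``) so perfectly
    regular sessions stay finite.  Fewer than ``min_intervals`` intervals
    (the sleep-sample eligibility rule) yields all-null features.
    """
    if len(intervals) < min_intervals:
        return RestSummaries(None, None, None)
    lengths = np.array([iv.duration_h for iv in intervals])
    mids = np.array([iv.midpoint_clock_h for iv in intervals])
    centre = circular_mean_h(mids)
    dev = (mids - centre + 12.0) % 24.0 - 12.0  # unwrap to (-12, 12]
    sd = float(np.std(dev, ddof=1))
    return RestSummaries(
        mean_length_h=float(lengths.mean()),
        midpoint_h=centre,
        log_midpoint_sd=float(np.log(sd + log_eps)),
    )


def self_report_midpoint(bed_h: float, wake_h: float) -> float | None:
    """Midpoint of the bed-to-wake arc going forward in time, in [0, 24).

    ``None`` when bed and wake coincide (undefined duration).
    """
    duration = (wake_h - bed_h) % 24.0
    if duration == 0.0:
        return None
    return (bed_h + duration / 2.0) % 24.0
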