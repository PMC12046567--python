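"""Actigraphy preprocessing: nonwear exclusion, 15 s -> 60 s downsampling,
rest/sleep-interval detection, and valid-day accounting.

The processing chain mirrors standard handling of wrist-worn count
accelerometers: runs of more than four consecutive hours with zero counts are
treated as device removal and the surrounding 24 h is excluded; the 15 s
series is anti-alias filtered (Hamming-window FIR) and decimated to 60 s
epochs; a nightly principal rest interval is detected per noon-to-noon day
with an adaptive log-count threshold plus morphological smoothing; and
sessions are admitted to the analytic samples only with at least five valid
recording (and, for sleep features, sleep) days.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .containers import EpochSeries, SleepInterval

NONWEAR_MIN_RUN_H = 4.0
NONWEAR_WINDOW_H = 24.0
MAX_SLEEP_H = 18.0
VALID_DAY_FRACTION = 0.9
MIN_VALID_DAYS = 5


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of exactly-zero counts as half-open index ranges."""
    zero = counts == 0
    if not zero.any():
        return []
    padded = np.concatenate(([False], zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def flag_nonwear(
    series: EpochSeries,
    min_run_h: float = NONWEAR_MIN_RUN_H,
    window_h: float = NONWEAR_WINDOW_H,
) -> EpochSeries:
    """Mask nonwear: zero-count runs strictly longer than ``min_run_h`` hours.

    For each qualifying run the full ``window_h`` window centred on the run's
    midpoint is excluded (clipped to the recording).  Counts are left
    untouched; only the exclusion mask is updated (union with any existing
    exclusions).  Overlapping windows simply merge.
    """
    mask = series.excluded.copy()
    per_h = 3600.0 / series.epoch_s
    min_run = min_run_h * per_h
    half = window_h * per_h / 2.0
    for lo, hi in _zero_runs(series.counts):
        if hi - lo <= min_run:  # "strictly longer than" the threshold
            continue
        mid = (lo + hi) / 2.0
        a = max(0, int(np.floor(mid - half)))
        b = min(len(series), int(np.ceil(mid + half)))
        mask[a:b] = True
    return series.with_mask(mask)


def downsample_to_60s(series: EpochSeries, numtaps: int = 65) -> EpochSeries:
    """Decimate a 15 s series to 60 s epochs with a Hamming-window FIR filter.

    A ``numtaps``-tap zero-phase low-pass (cutoff at the new Nyquist,
    1/120 Hz) is applied before 4:1 decimation, so the 24 h rhythm passes
    essentially unattenuated while energy above the new Nyquist is rejected.
    A 60 s epoch is excluded when any of its four source epochs is excluded.
    Filtered counts are clipped at zero (counts are non-negative by
    definition; the FIR can undershoot at sharp edges).
    """
    if series.epoch_s != 15:
        raise ValueError("downsample_to_60s expects 15 s epochs")
    if len(series) < 3 * numtaps:
        raise ValueError("series shorter than the FIR filter warm-up")
    n4 = 4 * (len(series) // 4)
    taps = signal.firwin(numtaps, 0.25, window="hamming")  # cutoff = new Nyquist
    smooth = signal.filtfilt(taps, [1.0], series.counts[:n4])
    counts = np.clip(smooth[::4], 0.0, None)
    excluded = series.excluded[:n4].reshape(-1, 4).any(axis=1)
    return EpochSeries(
        subject=series.subject,
        session=series.session,
        start=series.start,
        epoch_s=60,
        counts=counts,
        excluded=excluded,
    )


def _two_means_threshold(x: np.ndarray, min_separation: float = 0.25) -> float | None:
    """Midpoint between the two centres of a 1-D 2-means split of ``x``.

    Deterministic Lloyd iteration initialised at the 10th/90th percentiles.
    Returns ``None`` when the split is degenerate (centres closer than
    ``min_separation`` log-units), i.e. the day has no bimodal
    rest/activity structure to threshold.
    """
    lo, hi = np.percentile(x, [10.0, 90.0])
    if hi - lo < min_separation:
        return None
    for _ in range(100):
        cut = (lo + hi) / 2.0
        low = x[x <= cut]
        high = x[x > cut]
        if len(low) == 0 or len(high) == 0:
            return None
        new_lo, new_hi = low.mean(), high.mean()
        if abs(new_lo - lo) < 1e-10 and abs(new_hi - hi) < 1e-10:
            break
        lo, hi = new_lo, new_hi
    if hi - lo < min_separation:
        return None
    return (lo + hi) / 2.0


def detect_sleep_intervals(
    series: EpochSeries,
    smooth_min: int = 30,
    max_duration_h: float = MAX_SLEEP_H,
    min_unmasked_frac: float = 0.5,
    low_count: float = 10.0,
) -> list[SleepInterval]:
    """Detect the principal nightly rest interval per noon-to-noon day.

    Per eligible day (>= ``min_unmasked_frac`` of epochs unmasked):
    log-transform counts as ln(count + 1); threshold at the midpoint between
    the two cluster centres of a 2-means split of the day's log-counts;
    morphologically open then close the binary rest signal with a
    ``smooth_min``-minute structuring element (opening removes sub-element
    rest flecks from noisy waking epochs, closing fills brief intrusions
    inside the bout); keep the longest rest bout.
    Bouts longer than ``max_duration_h`` (invalid, e.g. a device left on a
    table) are discarded.  Masked epochs count as active so nonwear zeros are
    never mistaken for sleep.

    When the day's log-counts have no 2-means structure (near-constant day),
    a fallback splits at ln(1 + ``low_count``): an all-quiet day becomes one
    >18 h bout and is discarded by the cap; a uniformly active day yields no
    rest and no interval.
    """
    if series.epoch_s != 60:
        raise ValueError("rest detection operates on 60 s epochs")
    log_counts = np.log1p(series.counts)
    day_ids = series.noon_day_ids()
    struct = np.ones(max(1, int(round(smooth_min * 60 / series.epoch_s))), dtype=bool)
    intervals: list[SleepInterval] = []
    for day in np.unique(day_ids):
        idx = np.flatnonzero(day_ids == day)
        unmasked = ~series.excluded[idx]
        if unmasked.mean() < min_unmasked_frac:
            continue
        x = log_counts[idx][unmasked]
        thr = _two_means_threshold(x)
        if thr is None:
            thr = np.log1p(low_count)
        rest = (log_counts[idx] < thr) & unmasked
        if not rest.any():
            continue
        rest = ndimage.binary_opening(rest, structure=struct)
        rest = ndimage.binary_closing(rest, structure=struct)
        bounds = _longest_true_run(rest)
        if bounds is None:
            continue
        lo, hi = bounds
        duration_h = (hi - lo) * series.epoch_s / 3600.0
        if duration_h <= 0 or duration_h > max_duration_h:
            continue
        intervals.append(
            SleepInterval(
                onset=series.time_at(idx[0] + lo),
                offset=series.time_at(idx[0] + hi),
            )
        )
    return intervals


def _longest_true_run(flags: np.ndarray) -> tuple[int, int] | None:
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    if len(edges) == 0:
        return None
    starts, ends = edges[::2], edges[1::2]
    k = int(np.argmax(ends - starts))
    return int(starts[k]), int(ends[k])


def count_valid_days(
    series: EpochSeries,
    intervals: Iterable[SleepInterval] = (),
    valid_fraction: float = VALID_DAY_FRACTION,
) -> tuple[int, int]:
    """Count valid recording days and valid sleep days (noon-to-noon).

    A recording day is valid when at least ``valid_fraction`` of its epochs
    are unmasked *and* the day is fully covered by the recording; a sleep day
    is a valid recording day whose window contains a detected interval onset.
    Sessions qualify for the rest-activity-rhythm sample with >= 5 valid
    recording days and for the sleep sample with >= 5 valid sleep days.
    """
    day_ids = series.noon_day_ids()
    epochs_per_day = int(round(24 * 3600 / series.epoch_s))
    valid_days: set[int] = set()
    for day in np.unique(day_ids):
        idx = day_ids == day
        if idx.sum() < epochs_per_day:  # partial leading/trailing day
            continue
        if (~series.excluded[idx]).mean() >= valid_fraction:
            valid_days.add(int(day))
    sleep_days: set[int] = set()
    if valid_days:
        # map each interval onset to the same noon-to-noon day indexing
        origin = series.start.normalize()
        abs_h0 = (series.start - origin) / pd.Timedelta(hours=1)
        base = int(np.floor((abs_h0 - 12.0) / 24.0))  # raw id of day 0
        for iv in intervals:
            onset_h = (iv.onset - origin) / pd.Timedelta(hours=1)
            d = int(np.floor((onset_h - 12.0) / 24.0)) - base
            if d in valid_days:
                sleep_days.add(d)
    return len(valid_days), len(sleep_days)


def session_is_eligible(
    valid_recording_days: int,
    valid_sleep_days: int,
    min_days: int = MIN_VALID_DAYS,
) -> tuple[bool, bool]:
    """(rest-activity-rhythm sample, sleep sample) eligibility flags."""
    return valid_recording_days >= min_days, valid_sleep_days >= min_days
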