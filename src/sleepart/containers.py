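"""In-memory containers for epoch-level actigraphy and detected rest intervals."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Hours from midnight to the noon day boundary.  Rest detection and valid-day
#: accounting use noon-to-noon days so a night's sleep is never split in two.
NOON_H = 12.0


@dataclass
class EpochSeries:
    """One recording session of integer activity counts at a fixed epoch length.

    Counts are accompanied by an exclusion mask (``True`` = excluded from
    analysis, e.g. flagged nonwear).  Timestamps are implicit:
    epoch *i* starts at ``start + i * epoch_s`` seconds.
    """

    subject: str
    session: str
    start: pd.Timestamp
    epoch_s: int
    counts: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.excluded is None:
            self.excluded = np.zeros(self.counts.shape, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.counts.shape != self.excluded.shape:
            raise ValueError("counts and exclusion mask must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")
        if self.epoch_s not in (15, 60):
            raise ValueError(f"unsupported epoch length: {self.epoch_s} s")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def duration_h(self) -> float:
        return len(self) * self.epoch_s / 3600.0

    def hours_from_start(self) -> np.ndarray:
        return np.arange(len(self)) * (self.epoch_s / 3600.0)

    def clock_hours(self) -> np.ndarray:
        """Clock time-of-day in hours for each epoch start, in [0, 24)."""
        start_h = (
            self.start.hour
            + self.start.minute / 60.0
            + self.start.second / 3600.0
        )
        return (start_h + self.hours_from_start()) % 24.0

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_s, unit="s"
        )

    def noon_day_ids(self) -> np.ndarray:
        """Integer noon-to-noon day index for each epoch (first day = 0).

        An epoch belongs to day *d* when its start lies in
        ``[noon_d, noon_{d+1})`` where the noons are absolute calendar noons.
        """
        origin = self.start.normalize()  # midnight of the start date
        abs_h = (self.start - origin) / pd.Timedelta(hours=1) + self.hours_from_start()
        day = np.floor((abs_h - NOON_H) / 24.0).astype(int)
        return day - day.min() if len(day) else day

    def with_mask(self, excluded: np.ndarray) -> "EpochSeries":
        return replace(self, excluded=np.asarray(excluded, dtype=bool).copy())

    def time_at(self, index: int) -> pd.Timestamp:
        """Timestamp of the start of epoch ``index`` (may be one past the end)."""
        return self.start + pd.Timedelta(seconds=int(index) * self.epoch_s)


def circular_midpoint(onset_clock_h: float, duration_h: float) -> float:
    """Clock time halfway along the forward arc from onset, in [0, 24)."""
    return (onset_clock_h + duration_h / 2.0) % 24.0


@dataclass(frozen=True)
class SleepInterval:
    """A detected principal rest interval (sleep onset to offset)."""

    onset: pd.Timestamp
    offset: pd.Timestamp

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must be after onset")
        if self.duration_h > 18.0:
            raise ValueError("rest intervals are capped at 18 h")

    @property
    def duration_h(self) -> float:
        return (self.offset - self.onset) / pd.Timedelta(hours=1)

    @property
    def onset_clock_h(self) -> float:
        t = self.onset
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    @property
    def midpoint_clock_h(self) -> float:
        """Circular midpoint of onset and offset clock times, in [0, 24)."""
        return circular_midpoint(self.onset_clock_h, self.duration_h)
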