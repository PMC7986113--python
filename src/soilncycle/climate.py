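"""Thermal-regime metrics from soil temperature logger series.

Reduces 30-minute logger records (and manual spot measurements) into the
summaries used to characterise a soil-cover treatment: period means,
afternoon (14:00-16:00) means, daily temperature amplitude, and counts of
freeze-thaw cycles around 0 degC, both raw (every zero transition, divided
by two) and with a +-threshold band that suppresses cycles from a sensor
oscillating within noise of zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "FreezeThawCount",
    "ClimateSummary",
    "EmptySelectionError",
    "read_logger_csv",
    "daily_amplitude",
    "count_freeze_thaw",
    "aggregate_period_mean",
    "average_spot_measurements",
    "climate_summary",
]

logger = logging.getLogger(__name__)

#: nominal logger cadence: 48 readings per day at 30 min
READINGS_PER_DAY = 48
#: a calendar day needs at least this many readings to yield an amplitude
MIN_READINGS_PER_DAY = 40

AFTERNOON_WINDOW = (time(14, 0), time(16, 0))  # half-open [14:00, 16:00)


class EmptySelectionError(ValueError):
    """A period/window selection matched no readings."""


@dataclass
class TemperatureSeries:
    """A per-plot (or per-logger) soil temperature record.

    ``data`` is a float Series indexed by a strictly increasing
    DatetimeIndex in logger local time; cadence gaps are allowed and
    recorded by the reductions that care about them, never interpolated.
    """

    plot_id: str
    data: pd.Series

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("empty temperature series")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("TemperatureSeries requires a DatetimeIndex")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("temperatures must be finite")

    @classmethod
    def from_arrays(cls, plot_id, timestamps, temps_c):
        return cls(plot_id, pd.Series(np.asarray(temps_c, dtype=float),
                                      index=pd.DatetimeIndex(timestamps)))


@dataclass
class FreezeThawCount:
    """Freeze-thaw cycle count: ``cycles`` full cycles (= transitions // 2),
    with an ``odd_transition`` remainder when the series ends mid-cycle."""

    cycles: int
    transitions: int
    threshold: float

    @property
    def odd_transition(self) -> bool:
        return self.transitions % 2 == 1


@dataclass
class ClimateSummary:
    plot_id: str
    monthly_mean: dict = field(default_factory=dict)
    monthly_amplitude: dict = field(default_factory=dict)
    summer_mean: float | None = None
    afternoon_mean: float | None = None
    freeze_thaw_raw: int | None = None
    freeze_thaw_thresholded: int | None = None
    moisture_mean: float | None = None


def read_logger_csv(path, plot_id: str | None = None) -> TemperatureSeries:
    """Read a logger CSV with columns (timestamp, temp_c); ';' or ','
    delimited, ISO-8601 timestamps."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected timestamp and temperature columns")
    ts, temp = df.columns[:2]
    series = pd.Series(df[temp].astype(float).to_numpy(),
                       index=pd.DatetimeIndex(pd.to_datetime(df[ts])))
    return TemperatureSeries(plot_id or str(path), series)


def daily_amplitude(series: TemperatureSeries,
                    min_readings_per_day: int = MIN_READINGS_PER_DAY) -> pd.Series:
    """Per-calendar-day temperature amplitude (max - min), in degC.

    Days with fewer than ``min_readings_per_day`` readings are omitted from
    the result and logged, since a partial day biases the amplitude low.
    """
    grouped = series.data.groupby(series.data.index.normalize())
    counts = grouped.count()
    keep = counts[counts >= min_readings_per_day].index
    dropped = counts.index.difference(keep)
    if len(dropped):
        logger.info("daily_amplitude(%s): omitting %d day(s) with <%d readings: %s",
                    series.plot_id, len(dropped), min_readings_per_day,
                    [d.date().isoformat() for d in dropped])
    amp = (grouped.max() - grouped.min()).loc[keep]
    amp.name = "amplitude_c"
    return amp


def _signs_with_zero_inheritance(temps: np.ndarray) -> np.ndarray:
    """Sign of each reading; an exact 0.0 inherits the previous sign (the
    first reading, if zero, counts as thawed). Avoids double-counting a
    logger that stores 0.0 while sitting on the freezing point."""
    signs = np.sign(temps)
    if signs[0] == 0:
        signs[0] = 1.0
    for i in range(1, len(signs)):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    return signs


def count_freeze_thaw(series: TemperatureSeries, threshold: float = 0.0,
                      mode: str = "hysteresis") -> FreezeThawCount:
    """Count freeze-thaw cycles of a temperature series.

    threshold = 0
        every sign change between consecutive readings is a transition;
        cycles = transitions // 2 (a freeze plus a thaw make one cycle).
    threshold > 0, mode="hysteresis" (default)
        a state machine flips to frozen only below -threshold and to thawed
        only above +threshold, so a full traversal of the +-threshold band
        is required; cycles = state flips // 2.
    threshold > 0, mode="band"
        only transitions that jump the whole band within one cadence step
        (from above +threshold to below -threshold or vice versa) count.

    The thresholded count can never exceed the raw count.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    temps = series.data.to_numpy(dtype=float)
    if threshold == 0.0:
        signs = _signs_with_zero_inheritance(temps)
        transitions = int(np.sum(signs[1:] != signs[:-1]))
    elif mode == "hysteresis":
        transitions = 0
        state = 0  # unknown until first exceedance
        for t in temps:
            if t > threshold:
                new = 1
            elif t < -threshold:
                new = -1
            else:
                continue
            if state != 0 and new != state:
                transitions += 1
            state = new
    elif mode == "band":
        transitions = 0
        for prev, cur in zip(temps[:-1], temps[1:]):
            if (prev > threshold and cur < -threshold) or \
               (prev < -threshold and cur > threshold):
                transitions += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    count = FreezeThawCount(cycles=transitions // 2, transitions=transitions,
                            threshold=threshold)
    if count.odd_transition:
        logger.info("count_freeze_thaw(%s): odd transition count %d "
                    "(series ends mid-cycle)", series.plot_id, transitions)
    return count


def aggregate_period_mean(series: TemperatureSeries, start, end,
                          window: tuple[time, time] | None = None) -> float:
    """Mean temperature over a date period, optionally restricted to a
    half-open daily time-of-day window (e.g. the 14:00-16:00 'afternoon').

    ``start``/``end`` bound the period inclusively (dates or datetimes).
    Raises :class:`EmptySelectionError` when nothing falls in the selection.
    """
    sel = series.data.loc[pd.Timestamp(start):pd.Timestamp(end)]
    if window is not None:
        lo, hi = window
        tod = sel.index.time
        sel = sel[(tod >= lo) & (tod < hi)]
    if len(sel) == 0:
        raise EmptySelectionError(
            f"no readings for {series.plot_id} in [{start}, {end}]"
            + (f" window {window}" if window else ""))
    return float(sel.mean())


def average_spot_measurements(df: pd.DataFrame, value: str = "value") -> pd.Series:
    """Per-plot mean of repeated spot measurements.

    Expects tidy columns (plot_id, visit, value): the within-visit
    replicates are averaged first, then the per-visit means averaged across
    visits — equal to the flat mean when visits are balanced, and the
    correct visit-weighted mean when they are not.
    """
    for col in ("plot_id", "visit", value):
        if col not in df.columns:
            raise ValueError(f"spot-measurement table missing column {col!r}")
    per_visit = df.groupby(["plot_id", "visit"])[value].mean()
    out = per_visit.groupby("plot_id").mean()
    out.name = value
    return out


def climate_summary(series: TemperatureSeries, threshold: float = 0.1,
                    summer=("06-01", "08-31"), year: int | None = None,
                    min_readings_per_day: int = MIN_READINGS_PER_DAY) -> ClimateSummary:
    """One-stop reduction of a logger series to its ClimateSummary."""
    s = series.data
    monthly = s.groupby(s.index.to_period("M")).mean()
    amp = daily_amplitude(series, min_readings_per_day)
    monthly_amp = amp.groupby(amp.index.to_period("M")).mean() if len(amp) else pd.Series(dtype=float)
    years = sorted(set(s.index.year))
    yr = year if year is not None else years[-1]
    try:
        smean = aggregate_period_mean(series, f"{yr}-{summer[0]}", f"{yr}-{summer[1]} 23:59:59")
    except EmptySelectionError:
        smean = None
    try:
        july_aft = aggregate_period_mean(series, f"{yr}-07-01", f"{yr}-07-31 23:59:59",
                                         window=AFTERNOON_WINDOW)
    except EmptySelectionError:
        july_aft = None
    return ClimateSummary(
        plot_id=series.plot_id,
        monthly_mean={str(k): float(v) for k, v in monthly.items()},
        monthly_amplitude={str(k): float(v) for k, v in monthly_amp.items()},
        summer_mean=smean,
        afternoon_mean=july_aft,
        freeze_thaw_raw=count_freeze_thaw(series, 0.0).cycles,
        freeze_thaw_thresholded=count_freeze_thaw(series, threshold).cycles,
    )
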