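"""Submergence-duration statistics and threshold actuation schedules.

Given a realized water-level series and a simulated shore elevation (the
tidal height of a pot's soil surface), a sample counts as *submerged* when
the water level is at or above the elevation — water exactly at soil height
counts.  Each sample represents one sampling interval, so submerged hours
are ``count * step / 3600``; "days" are local calendar days (midnight
boundaries) containing at least one submerged sample.

The same boolean classification drives actuation schedules for valve or
spray control: alternating above/below intervals that tile the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .engine import TideSeries
from .errors import MesotideError


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _round1_half_up(x: float) -> float:
    return math.floor(x * 10 + 0.5) / 10


@dataclass(frozen=True)
class SubmergenceRow:
    """Submergence summary for one shore elevation.

    ``total_hours`` is rounded half-up to an integer for display;
    ``hours_exact`` keeps full precision and is what ``percent_time`` is
    computed from (rounded to 1 decimal).  ``submerged_seconds`` is the
    exactly-representable sample count times step, the quantity the
    actuation schedule's above-interval durations sum to exactly.
    """

    elevation: float
    days_with_event: int
    total_hours: int
    percent_time: float
    hours_exact: float
    submerged_seconds: float


@dataclass(frozen=True)
class ActuationInterval:
    """One above- or below-threshold stretch of the series."""

    start: datetime
    end: datetime
    state: Literal["above", "below"]

    @property
    def duration_seconds(self) -> float:
        return (self.end - self.start).total_seconds()


def submergence_report(
    series: TideSeries, elevations: Sequence[float]
) -> list[SubmergenceRow]:
    """One summary row per shore elevation (days with an event, hours, percent)."""
    elevations = [float(e) for e in elevations]
    if any(not math.isfinite(e) for e in elevations):
        raise MesotideError("elevations must be finite")
    h = series.heights
    dates = np.array([t.date() for t in series.times().to_pydatetime()])
    total_hours = series.duration_hours
    rows = []
    for elev in elevations:
        submerged = h >= elev
        seconds = float(submerged.sum()) * series.step
        hours = seconds / 3600.0
        days = len(set(dates[submerged]))
        percent = _round1_half_up(100.0 * hours / total_hours)
        rows.append(
            SubmergenceRow(
                elevation=elev,
                days_with_event=days,
                total_hours=_round_half_up(hours),
                percent_time=percent,
                hours_exact=hours,
                submerged_seconds=seconds,
            )
        )
    return rows


def threshold_schedule(
    series: TideSeries, threshold: float
) -> list[ActuationInterval]:
    """Alternating above/below intervals tiling the series.

    The state flips exactly at the first sample whose classification
    (``height >= threshold``) differs from the previous sample's; the final
    interval ends at ``start + n*step`` so the intervals cover the same
    duration the report accounts for.  The sum of above-interval durations
    equals the submerged seconds of :func:`submergence_report` exactly.
    """
    above = series.heights >= threshold
    flips = np.flatnonzero(above[1:] != above[:-1]) + 1
    bounds = [0, *flips.tolist(), len(series)]
    intervals = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        intervals.append(
            ActuationInterval(
                start=series.time_at(i0),
                end=series.time_at(i1),
                state="above" if above[i0] else "below",
            )
        )
    return intervals


def report_to_csv(rows: list[SubmergenceRow], path) -> None:
    """Write `elevation_m,days_with_event,total_hours,percent_time` CSV."""
    df = pd.DataFrame(
        {
            "elevation_m": [r.elevation for r in rows],
            "days_with_event": [r.days_with_event for r in rows],
            "total_hours": [r.total_hours for r in rows],
            "percent_time": [r.percent_time for r in rows],
        }
    )
    df.to_csv(path, index=False)


def schedule_to_csv(intervals: list[ActuationInterval], path) -> None:
    """Write `start,end,state` CSV."""
    df = pd.DataFrame(
        {
            "start": [iv.start.isoformat() for iv in intervals],
            "end": [iv.end.isoformat() for iv in intervals],
            "state": [iv.state for iv in intervals],
        }
    )
    df.to_csv(path, index=False)
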