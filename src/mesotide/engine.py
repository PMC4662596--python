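"""Harmonic tide synthesis, series generation and high/low tide detection.

The predicted height above MLLW at time ``t`` is the standard harmonic sum

    h(t) = Z0 + sum_i f_i * A_i * cos( omega_i * tau + (V0+u)_i - kappa_i )

with all angles in degrees and ``tau`` the fractional hours elapsed since
local-standard midnight of Jan 1 of ``t``'s year (the epoch the per-year
node factors f and equilibrium arguments V0+u are referenced to).  Angles
are converted to radians only inside the cosine.

Timestamps are naive local standard time throughout; there is no daylight
saving anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .errors import MesotideError
from .harmonics import StationHarmonics

DEG = math.pi / 180.0


@dataclass(frozen=True)
class TideSeries:
    """A regularly sampled tide-height series.

    Sample ``k`` is at ``start + k*step`` seconds; ``heights`` are meters
    above MLLW.  For duration accounting each sample represents the
    half-open interval ``[t_k, t_k + step)``, so the series covers
    ``n * step`` seconds in total.
    """

    start: datetime
    step: float
    heights: np.ndarray = field(repr=False)

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "heights", h)
        if self.step <= 0:
            raise MesotideError(f"step must be > 0, got {self.step}")
        if h.ndim != 1 or h.size == 0:
            raise MesotideError("heights must be a non-empty 1-D array")
        if not np.all(np.isfinite(h)):
            raise MesotideError("heights must all be finite")

    def __len__(self) -> int:
        return self.heights.size

    def time_at(self, k: int) -> datetime:
        return self.start + timedelta(seconds=float(k * self.step))

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=len(self), freq=pd.Timedelta(seconds=self.step)
        )

    @property
    def duration_hours(self) -> float:
        """Total covered duration (sample-as-interval), in hours."""
        return len(self) * self.step / 3600.0


@dataclass(frozen=True)
class TideEvent:
    """One high or low tide."""

    time: datetime
    height: float
    kind: Literal["high", "low"]


def _tau_hours(t: datetime) -> float:
    """Fractional hours since local-standard midnight Jan 1 of t's year."""
    epoch = datetime(t.year, 1, 1)
    return (t - epoch).total_seconds() / 3600.0


def predict_height(station: StationHarmonics, t: datetime) -> float:
    """Predicted tide height (m above MLLW) at one timestamp."""
    yc = station.corrections_for(t.year)
    tau = _tau_hours(t)
    h = station.datum_offset
    for c, f, vu in zip(station.constituents, yc.node_factors, yc.equilibrium_args):
        h += f * c.amplitude * math.cos((c.speed * tau + vu - c.phase_lag) * DEG)
    return h


def _heights_for_year(
    station: StationHarmonics, year: int, tau: np.ndarray
) -> np.ndarray:
    """Vectorized synthesis for an array of within-year epochs (hours)."""
    yc = station.corrections_for(year)
    h = np.full(tau.shape, station.datum_offset)
    for c, f, vu in zip(station.constituents, yc.node_factors, yc.equilibrium_args):
        h += f * c.amplitude * np.cos((c.speed * tau + vu - c.phase_lag) * DEG)
    return h


def _year_segments(
    start: datetime, step: float, n: int
) -> Iterator[tuple[int, int, int]]:
    """Yield (year, first sample index, one-past-last) for a uniform grid."""
    k0 = 0
    year = start.year
    while k0 < n:
        boundary = datetime(year + 1, 1, 1)
        # first sample index at or after the next Jan 1
        k1 = math.ceil(((boundary - start).total_seconds() - 1e-9) / step)
        k1 = min(max(k1, k0 + 1), n)
        yield year, k0, k1
        k0 = k1
        year += 1


def predict_series(
    station: StationHarmonics,
    start: datetime,
    end: datetime,
    step: float = 60.0,
) -> TideSeries:
    """Predict heights on a uniform grid from start to end inclusive.

    Sample count is ``floor((end-start)/step) + 1``.  Every covered year
    must have a correction table; the canonical controller cadence is a
    60 s step.
    """
    if end <= start:
        raise MesotideError(f"end ({end}) must be after start ({start})")
    if step <= 0:
        raise MesotideError(f"step must be > 0, got {step}")
    n = int(math.floor((end - start).total_seconds() / step + 1e-9)) + 1
    heights = np.empty(n)
    for year, k0, k1 in _year_segments(start, step, n):
        epoch = datetime(year, 1, 1)
        off = (start - epoch).total_seconds()
        tau = (off + np.arange(k0, k1) * step) / 3600.0
        heights[k0:k1] = _heights_for_year(station, year, tau)
    return TideSeries(start=start, step=step, heights=heights)


def _derivative(station: StationHarmonics, t: datetime) -> float:
    """dh/dt in meters per hour at t (analytic)."""
    yc = station.corrections_for(t.year)
    tau = _tau_hours(t)
    d = 0.0
    for c, f, vu in zip(station.constituents, yc.node_factors, yc.equilibrium_args):
        d -= (
            f
            * c.amplitude
            * c.speed
            * DEG
            * math.sin((c.speed * tau + vu - c.phase_lag) * DEG)
        )
    return d


def find_extrema(
    station: StationHarmonics,
    start: datetime,
    end: datetime,
    *,
    grid_step: float = 60.0,
    time_tol: float = 1.0,
) -> list[TideEvent]:
    """Locate high and low tides between start and end.

    Candidates come from sign changes of the first difference on a
    ``grid_step`` (default 1 minute) grid; each is refined to ``time_tol``
    seconds (default 1 s) by root-finding on the analytic derivative, with a
    bounded golden-section fallback where the derivative does not bracket.
    Ties (flat stretches) resolve to the earliest time.  Returned events
    alternate high/low.
    """
    series = predict_series(station, start, end, grid_step)
    h = series.heights
    d = np.diff(h)
    sign = np.sign(d)
    # carry the previous nonzero sign through flat stretches
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    events: list[TideEvent] = []

    def h_at(sec: float) -> float:
        return predict_height(station, start + timedelta(seconds=sec))

    def d_at(sec: float) -> float:
        return _derivative(station, start + timedelta(seconds=sec))

    for k in np.flatnonzero(sign[:-1] != sign[1:]):
        kind = "high" if sign[k] > 0 else "low"
        lo = k * grid_step
        hi = (k + 2) * grid_step
        dlo, dhi = d_at(lo), d_at(hi)
        if dlo == 0.0:
            sec = lo
        elif dlo * dhi < 0:
            sec = brentq(d_at, lo, hi, xtol=time_tol)
        else:
            obj = (lambda x: -h_at(x)) if kind == "high" else h_at
            res = minimize_scalar(
                obj, bounds=(lo, hi), method="bounded",
                options={"xatol": time_tol},
            )
            sec = float(res.x)
        t = start + timedelta(seconds=round(sec))
        events.append(TideEvent(time=t, height=predict_height(station, t), kind=kind))

    # enforce alternation: among consecutive same-kind events keep the extreme one
    cleaned: list[TideEvent] = []
    for ev in events:
        if cleaned and cleaned[-1].kind == ev.kind:
            keep_new = (
                ev.height > cleaned[-1].height
                if ev.kind == "high"
                else ev.height < cleaned[-1].height
            )
            if keep_new:
                cleaned[-1] = ev
        else:
            cleaned.append(ev)
    return cleaned


# ---------------------------------------------------------------------------
# CSV interchange

def series_to_csv(series: TideSeries, path) -> None:
    """Write `timestamp,height_m` CSV (ISO 8601 naive local timestamps)."""
    df = pd.DataFrame(
        {
            "timestamp": [t.isoformat() for t in series.times().to_pydatetime()],
            "height_m": np.round(series.heights, 6),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def series_from_csv(path) -> TideSeries:
    """Read a series CSV written by :func:`series_to_csv`."""
    df = pd.read_csv(path)
    for col in ("timestamp", "height_m"):
        if col not in df.columns:
            raise MesotideError(f"{path}: series CSV missing column {col!r}")
    times = pd.to_datetime(df["timestamp"])
    if len(times) < 2:
        raise MesotideError(f"{path}: series CSV needs at least 2 samples")
    steps = np.diff(times.to_numpy()).astype("timedelta64[ns]").astype(float) / 1e9
    if not np.allclose(steps, steps[0]):
        raise MesotideError(f"{path}: series CSV is not uniformly sampled")
    return TideSeries(
        start=times.iloc[0].to_pydatetime(),
        step=float(steps[0]),
        heights=df["height_m"].to_numpy(float),
    )


def events_to_csv(events: list[TideEvent], path) -> None:
    """Write `timestamp,height_m,kind` CSV."""
    df = pd.DataFrame(
        {
            "timestamp": [e.time.isoformat() for e in events],
            "height_m": [round(e.height, 6) for e in events],
            "kind": [e.kind for e in events],
        }
    )
    df.to_csv(path, index=False)
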