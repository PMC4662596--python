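"""Synthetic stations and reference series.

Everything downstream (engine, rack, submergence, CLI) is testable offline
against fixtures built here: a single-constituent station with a closed-form
prediction, a seeded mixed-semidiurnal station with a realistic beat
structure (two unequal highs and two unequal lows per ~24.84 h lunar day),
and an exactly-countable square-wave series for submergence oracles.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np

from .engine import TideSeries
from .errors import MesotideError
from .harmonics import Constituent, StationHarmonics, YearCorrections

#: Standard published angular speeds, degrees per hour.
SPEEDS = {
    "M2": 28.9841042,   # principal lunar semidiurnal
    "S2": 30.0,         # principal solar semidiurnal
    "N2": 28.4397295,   # larger lunar elliptic semidiurnal
    "K1": 15.0410686,   # lunisolar diurnal
    "O1": 13.9430356,   # lunar diurnal
    "SA": 0.0410686,    # solar annual (long-period)
}


def _hours_in_year(year: int) -> int:
    return int(
        (datetime(year + 1, 1, 1) - datetime(year, 1, 1)).total_seconds() / 3600
    )


def _consistent_year_tables(
    constituents: tuple[Constituent, ...],
    years: tuple[int, ...],
    node_factors: np.ndarray,
    first_equilibrium: np.ndarray,
) -> dict[int, YearCorrections]:
    """Year tables whose equilibrium arguments advance coherently across Jan 1.

    With the within-year epoch convention, continuity across a year boundary
    requires (V0+u) of year y+1 to equal (V0+u) of year y plus omega times
    the hours in year y (mod 360); tables built here satisfy that, so a
    multi-year synthesis has no artificial jump at new year.
    """
    speeds = np.array([c.speed for c in constituents])
    tables = {}
    vu = np.asarray(first_equilibrium, dtype=float) % 360.0
    for y in years:
        tables[y] = YearCorrections(
            year=y,
            node_factors=tuple(node_factors),
            equilibrium_args=tuple(vu),
        )
        vu = (vu + speeds * _hours_in_year(y)) % 360.0
    return tables


def make_single_constituent_station(
    amplitude: float,
    speed: float,
    phase: float = 0.0,
    datum: float = 0.0,
    year: int = 2013,
    *,
    name: str = "SYN",
    n_years: int = 1,
) -> StationHarmonics:
    """Station with one constituent, f=1 and V0+u=0 for the given year.

    Its prediction has the closed form ``Z0 + A*cos(omega*tau - kappa)``,
    making it the oracle source for engine tests.
    """
    c = Constituent(name=name, amplitude=amplitude, phase_lag=phase, speed=speed)
    tables = _consistent_year_tables(
        (c,), tuple(range(year, year + n_years)), np.ones(1), np.zeros(1)
    )
    return StationHarmonics(
        station_name="synthetic single-constituent",
        station_id="SYN-1",
        datum_offset=datum,
        utc_offset_hours=-8.0,
        constituents=(c,),
        year_corrections=tables,
    )


def make_mixed_semidiurnal_station(
    seed: int, *, years: tuple[int, ...] = (2013, 2014)
) -> StationHarmonics:
    """Seeded station emulating a mixed semidiurnal regime.

    Five constituents — two semidiurnal (M2, S2), two diurnal (K1, O1) and
    one long-period (SA) — at their standard speeds, with amplitudes and
    phases drawn from the seed within ranges typical of a southern
    California estuary station (amplitude sum ~1.0-1.5 m over a ~0.87 m
    mean-level datum offset).  Deterministic for a given seed; for generic
    seeds the diurnal inequality gives two unequal highs and two unequal
    lows per lunar day.
    """
    rng = np.random.default_rng(seed)
    amp_ranges = {
        "M2": (0.45, 0.65),
        "S2": (0.15, 0.28),
        "K1": (0.25, 0.40),
        "O1": (0.15, 0.25),
        "SA": (0.03, 0.08),
    }
    constituents = tuple(
        Constituent(
            name=n,
            amplitude=float(rng.uniform(*amp_ranges[n])),
            phase_lag=float(rng.uniform(0.0, 360.0)),
            speed=SPEEDS[n],
        )
        for n in ("M2", "S2", "K1", "O1", "SA")
    )
    tables = _consistent_year_tables(
        constituents,
        tuple(years),
        np.ones(len(constituents)),
        rng.uniform(0.0, 360.0, size=len(constituents)),
    )
    return StationHarmonics(
        station_name=f"synthetic mixed semidiurnal (seed {seed})",
        station_id=f"SYN-MIXED-{seed}",
        datum_offset=0.87,
        utc_offset_hours=-8.0,
        constituents=constituents,
        year_corrections=tables,
    )


def make_square_wave_series(
    period_hours: float,
    duty_fraction: float,
    days: int,
    step: float = 60.0,
    *,
    high: float = 2.0,
    low: float = 0.0,
    start: datetime = datetime(2013, 1, 1),
) -> TideSeries:
    """Square wave: the first ``duty_fraction`` of each period sits at ``high``.

    For any threshold in ``(low, high]`` the above-threshold duration is
    exactly the number of high samples times the step — countable by
    construction, which makes this the submergence oracle input.
    """
    if not 0 < duty_fraction < 1:
        raise MesotideError(
            f"duty_fraction must be in (0, 1), got {duty_fraction}"
        )
    n = int(round(days * 86400 / step))
    t = np.arange(n) * step
    period = period_hours * 3600.0
    heights = np.where((t % period) < duty_fraction * period, high, low)
    return TideSeries(start=start, step=step, heights=heights.astype(float))
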