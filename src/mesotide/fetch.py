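"""Optional NOAA CO-OPS fetch helper (network; excluded from offline tests).

Translates a station's published harmonic constituents into the native
station schema.  NOAA's harcon product supplies amplitude (m), phase lag
(deg) and speed (deg/hr) per constituent; the caller supplies the per-year
node factors and equilibrium arguments (or accepts f=1, V0+u=0 stubs to be
filled in from an external table), because computing them from orbital
elements is outside this package's scope.
"""

from __future__ import annotations

import json
import urllib.request

from .errors import MesotideError
from .harmonics import Constituent, StationHarmonics, YearCorrections

HARCON_URL = (
    "https://api.tidesandcurrents.noaa.gov/mdapi/prod/webapi/stations/"
    "{station_id}/harcon.json?units=metric"
)
DATUMS_URL = (
    "https://api.tidesandcurrents.noaa.gov/mdapi/prod/webapi/stations/"
    "{station_id}/datums.json?units=metric"
)


def fetch_station(
    station_id: str, years: list[int], *, timeout: float = 30.0
) -> StationHarmonics:
    """Fetch a station's constituents and MLLW-referenced datum from NOAA.

    Year tables are stubbed with f=1, V0+u=0 for each requested year and
    must be replaced with real astronomical corrections before the station
    can reproduce published predictions.
    """
    try:
        with urllib.request.urlopen(
            HARCON_URL.format(station_id=station_id), timeout=timeout
        ) as resp:
            harcon = json.load(resp)
        with urllib.request.urlopen(
            DATUMS_URL.format(station_id=station_id), timeout=timeout
        ) as resp:
            datums = json.load(resp)
    except OSError as exc:
        raise MesotideError(f"NOAA fetch failed for {station_id}: {exc}") from None

    constituents = tuple(
        Constituent(
            name=h["name"],
            amplitude=float(h["amplitude"]),
            phase_lag=float(h["phase_GMT"]) % 360.0,
            speed=float(h["speed"]),
        )
        for h in harcon.get("HarmonicConstituents", [])
        if float(h["amplitude"]) > 0
    )
    if not constituents:
        raise MesotideError(f"NOAA returned no harmonic constituents for {station_id}")
    msl = next(
        (float(d["value"]) for d in datums.get("datums", []) if d.get("name") == "MSL"),
        0.0,
    )
    n = len(constituents)
    tables = {
        y: YearCorrections(
            year=y, node_factors=(1.0,) * n, equilibrium_args=(0.0,) * n
        )
        for y in years
    }
    return StationHarmonics(
        station_name=f"NOAA {station_id}",
        station_id=station_id,
        datum_offset=msl,
        utc_offset_hours=0.0,
        constituents=constituents,
        year_corrections=tables,
    )
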