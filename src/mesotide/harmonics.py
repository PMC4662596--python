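"""Station harmonic-constituent data model and file I/O.

A tide station is parameterized by a set of harmonic constituents — each a
sinusoid with amplitude ``A`` (m), Greenwich phase lag ``kappa`` (deg) and
angular speed ``omega`` (deg/hr) — plus per-calendar-year astronomical
corrections: a node factor ``f`` (unitless amplitude multiplier for the
18.6-year lunar nodal cycle) and an equilibrium argument ``V0+u`` (deg, the
phase of the astronomical forcing at the start of the year).  The datum
offset ``Z0`` is the height of mean water level above MLLW, the zero tidal
datum.

The native station file is JSON (see ``docs/station_schema.md``).  Heights
are meters internally; a file-level ``units`` flag of ``"ft"`` is converted
once on load.  The equilibrium arguments are referenced to local standard
midnight of Jan 1 of each tabulated year, and all timestamps everywhere in
the package are naive local standard time (no daylight saving).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .errors import (
    StationSchemaError,
    StationValidationError,
    UnsupportedYearError,
    YearAlignmentError,
)

FT_TO_M = 0.3048


def _require_finite(value: float, what: str) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise StationValidationError(f"{what} must be finite, got {value!r}")
    return v


@dataclass(frozen=True)
class Constituent:
    """One harmonic constituent: amplitude (m), phase lag (deg), speed (deg/hr)."""

    name: str
    amplitude: float
    phase_lag: float
    speed: float

    def __post_init__(self):
        _require_finite(self.amplitude, f"constituent {self.name!r} amplitude")
        _require_finite(self.phase_lag, f"constituent {self.name!r} phase_lag")
        _require_finite(self.speed, f"constituent {self.name!r} speed")
        if self.amplitude < 0:
            raise StationValidationError(
                f"constituent {self.name!r}: amplitude must be >= 0, got {self.amplitude}"
            )
        if self.speed <= 0:
            raise StationValidationError(
                f"constituent {self.name!r}: speed must be > 0, got {self.speed}"
            )
        if not 0 <= self.phase_lag < 360:
            raise StationValidationError(
                f"constituent {self.name!r}: phase_lag must be in [0, 360), got {self.phase_lag}"
            )


@dataclass(frozen=True)
class YearCorrections:
    """Node factors f_i and equilibrium arguments (V0+u)_i for one calendar year.

    Both tuples are index-aligned with the station's constituent list; the
    alignment is checked by :meth:`StationHarmonics.validate`.
    """

    year: int
    node_factors: tuple[float, ...]
    equilibrium_args: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "node_factors", tuple(float(x) for x in self.node_factors))
        object.__setattr__(
            self, "equilibrium_args", tuple(float(x) for x in self.equilibrium_args)
        )
        for i, f in enumerate(self.node_factors):
            _require_finite(f, f"year {self.year} node_factors[{i}]")
            if f <= 0:
                raise StationValidationError(
                    f"year {self.year}: node_factors[{i}] must be > 0, got {f}"
                )
        for i, v in enumerate(self.equilibrium_args):
            _require_finite(v, f"year {self.year} equilibrium_args[{i}]")


@dataclass(frozen=True)
class StationHarmonics:
    """Complete parameterization of a tide station.

    ``datum_offset`` (Z0) is meters of mean water level above MLLW;
    ``utc_offset_hours`` is metadata only — all arithmetic happens in local
    standard time, so no zone conversion ever occurs at predict time.
    """

    station_name: str
    station_id: str
    datum_offset: float
    utc_offset_hours: float
    constituents: tuple[Constituent, ...]
    year_corrections: dict[int, YearCorrections] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "constituents", tuple(self.constituents))
        object.__setattr__(
            self, "year_corrections", dict(self.year_corrections)
        )
        self.validate()

    def validate(self) -> None:
        _require_finite(self.datum_offset, "datum_offset")
        _require_finite(self.utc_offset_hours, "utc_offset_hours")
        if self.datum_offset < 0:
            raise StationValidationError(
                f"datum_offset must be >= 0, got {self.datum_offset}"
            )
        names = [c.name for c in self.constituents]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise StationValidationError(f"duplicate constituent names: {dupes}")
        n = len(self.constituents)
        for year, yc in self.year_corrections.items():
            if year != yc.year:
                raise YearAlignmentError(
                    f"year table keyed {year} declares year {yc.year}"
                )
            if len(yc.node_factors) != n:
                raise YearAlignmentError(
                    f"year {year}: node_factors has {len(yc.node_factors)} entries "
                    f"but the station has {n} constituents"
                )
            if len(yc.equilibrium_args) != n:
                raise YearAlignmentError(
                    f"year {year}: equilibrium_args has {len(yc.equilibrium_args)} entries "
                    f"but the station has {n} constituents"
                )

    @property
    def supported_years(self) -> list[int]:
        return sorted(self.year_corrections)

    def corrections_for(self, year: int) -> YearCorrections:
        try:
            return self.year_corrections[year]
        except KeyError:
            raise UnsupportedYearError(year, self.supported_years) from None

    @property
    def amplitude_sum(self) -> float:
        """Max possible |h - Z0| over supported years: max_year sum_i f_i A_i."""
        best = 0.0
        for yc in self.year_corrections.values():
            s = sum(f * c.amplitude for f, c in zip(yc.node_factors, self.constituents))
            best = max(best, s)
        return best


_STATION_KEYS = {
    "station_name",
    "station_id",
    "units",
    "datum_offset",
    "utc_offset_hours",
    "constituents",
    "years",
}
_CONSTITUENT_KEYS = {"name", "amplitude", "phase_lag", "speed"}
_YEAR_KEYS = {"node_factors", "equilibrium_args"}


def _check_keys(obj: dict, required: set[str], where: str) -> None:
    if not isinstance(obj, dict):
        raise StationSchemaError(f"{where}: expected a JSON object")
    missing = required - obj.keys()
    extra = obj.keys() - required
    if missing:
        raise StationSchemaError(f"{where}: missing field(s) {sorted(missing)}")
    if extra:
        raise StationSchemaError(f"{where}: unknown field(s) {sorted(extra)}")


def station_from_dict(doc: dict) -> StationHarmonics:
    """Build and validate a station from the native JSON schema (as a dict)."""
    _check_keys(doc, _STATION_KEYS, "station file")
    units = doc["units"]
    if units not in ("m", "ft"):
        raise StationSchemaError(f"units must be 'm' or 'ft', got {units!r}")
    scale = 1.0 if units == "m" else FT_TO_M
    constituents = []
    for i, c in enumerate(doc["constituents"]):
        _check_keys(c, _CONSTITUENT_KEYS, f"constituents[{i}]")
        constituents.append(
            Constituent(
                name=str(c["name"]),
                amplitude=float(c["amplitude"]) * scale,
                phase_lag=float(c["phase_lag"]),
                speed=float(c["speed"]),
            )
        )
    years: dict[int, YearCorrections] = {}
    for key, tab in doc["years"].items():
        try:
            year = int(key)
        except ValueError:
            raise StationSchemaError(f"years: non-integer year key {key!r}") from None
        _check_keys(tab, _YEAR_KEYS, f"years[{key}]")
        years[year] = YearCorrections(
            year=year,
            node_factors=tuple(float(x) for x in tab["node_factors"]),
            equilibrium_args=tuple(float(x) for x in tab["equilibrium_args"]),
        )
    return StationHarmonics(
        station_name=str(doc["station_name"]),
        station_id=str(doc["station_id"]),
        datum_offset=float(doc["datum_offset"]) * scale,
        utc_offset_hours=float(doc["utc_offset_hours"]),
        constituents=tuple(constituents),
        year_corrections=years,
    )


def station_to_dict(station: StationHarmonics) -> dict:
    """Serialize a station to the native schema (always meters)."""
    return {
        "station_name": station.station_name,
        "station_id": station.station_id,
        "units": "m",
        "datum_offset": station.datum_offset,
        "utc_offset_hours": station.utc_offset_hours,
        "constituents": [
            {
                "name": c.name,
                "amplitude": c.amplitude,
                "phase_lag": c.phase_lag,
                "speed": c.speed,
            }
            for c in station.constituents
        ],
        "years": {
            str(year): {
                "node_factors": list(yc.node_factors),
                "equilibrium_args": list(yc.equilibrium_args),
            }
            for year, yc in sorted(station.year_corrections.items())
        },
    }


def load_station(path) -> StationHarmonics:
    """Load and fully validate a station harmonics JSON file."""
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise StationSchemaError(f"{path}: not valid JSON ({exc})") from None
    return station_from_dict(doc)


def save_station(station: StationHarmonics, path) -> None:
    """Write a station to the native JSON schema; round-trips losslessly.

    Floats are serialized with ``repr`` precision, so ``load(save(s)) == s``
    bit-for-bit for any valid station already in meters.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(station_to_dict(station), fh, indent=2)
        fh.write("\n")
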