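"""Exception hierarchy for mesotide.

All errors raised on bad user input derive from :class:`MesotideError`,
itself a ``ValueError``, so callers can catch one base class.
"""


class MesotideError(ValueError):
    """Base class for all mesotide input/validation errors."""


class StationSchemaError(MesotideError):
    """A station file is missing a required field or carries an unknown one."""


class StationValidationError(MesotideError):
    """A station field violates its invariant (negative amplitude, non-finite value, ...)."""


class YearAlignmentError(MesotideError):
    """A per-year correction table is not index-aligned with the constituent list."""


class UnsupportedYearError(MesotideError):
    """A prediction was requested for a year with no correction table."""

    def __init__(self, year: int, supported: list[int]):
        self.year = year
        self.supported = sorted(supported)
        if self.supported:
            rng = f"{self.supported[0]}..{self.supported[-1]}"
        else:
            rng = "none"
        super().__init__(
            f"no astronomical correction table for year {year}; supported years: {rng}"
        )
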