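from datetime import datetime

import pytest

from mesotide import (
    SPEEDS,
    Constituent,
    StationHarmonics,
    YearCorrections,
    make_mixed_semidiurnal_station,
    make_single_constituent_station,
)


@pytest.fixture
def m2_station():
    """Pure M2 cosine: h(t) = cos(omega * tau), zero datum."""
    return make_single_constituent_station(1.0, SPEEDS["M2"], 0.0, 0.0, 2013)


@pytest.fixture
def mixed_station():
    return make_mixed_semidiurnal_station(1)


@pytest.fixture
def three_constituent_station():
    """Fixed small station used against the frozen direct-summation value."""
    cons = (
        Constituent("M2", 0.6, 120.0, 28.9841042),
        Constituent("S2", 0.25, 300.0, 30.0),
        Constituent("K1", 0.3, 45.0, 15.0410686),
    )
    return StationHarmonics(
        station_name="three-term test station",
        station_id="TEST-3",
        datum_offset=0.5,
        utc_offset_hours=-8.0,
        constituents=cons,
        year_corrections={
            2013: YearCorrections(
                year=2013,
                node_factors=(1.02, 1.00, 0.98),
                equilibrium_args=(35.0, 180.0, 200.0),
            )
        },
    )


@pytest.fixture
def jan1():
    return datetime(2013, 1, 1)
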