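"""Harmonic synthesis and extrema detection against closed forms and brute force."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesotide import (
    SPEEDS,
    Constituent,
    MesotideError,
    StationHarmonics,
    UnsupportedYearError,
    YearCorrections,
    find_extrema,
    make_single_constituent_station,
    predict_height,
    predict_series,
    series_from_csv,
    series_to_csv,
)

M2 = SPEEDS["M2"]


def direct_sum(station, t):
    """Independent term-by-term oracle: explicit fsum over the harmonic formula."""
    yc = station.year_corrections[t.year]
    tau = (t - datetime(t.year, 1, 1)).total_seconds() / 3600.0
    return station.datum_offset + math.fsum(
        f * c.amplitude * math.cos(math.radians(c.speed * tau + vu - c.phase_lag))
        for c, f, vu in zip(station.constituents, yc.node_factors, yc.equilibrium_args)
    )


class TestPredictHeight:
    def test_cosine_closed_form_at_tau_zero(self, m2_station, jan1):
        assert predict_height(m2_station, jan1) == pytest.approx(1.0, abs=1e-12)

    def test_cosine_zero_crossing_at_quarter_period(self, m2_station, jan1):
        t = jan1 + timedelta(hours=90.0 / M2)
        assert predict_height(m2_station, t) == pytest.approx(0.0, abs=1e-9)

    def test_three_constituent_value_matches_frozen_direct_summation(
        self, three_constituent_station
    ):
        t = datetime(2013, 7, 11, 14, 30)
        # frozen from an independent fsum evaluation of the harmonic formula
        assert predict_height(three_constituent_station, t) == pytest.approx(
            1.0147225016215264, rel=1e-12
        )
        assert predict_height(three_constituent_station, t) == pytest.approx(
            direct_sum(three_constituent_station, t), rel=1e-12
        )

    def test_missing_year_table_raises_unsupported_year(self, m2_station):
        with pytest.raises(UnsupportedYearError, match="2014"):
            predict_height(m2_station, datetime(2014, 6, 1))

    @settings(max_examples=60, deadline=None)
    @given(
        amps=st.lists(st.floats(0.0, 2.0), min_size=1, max_size=4),
        phases=st.lists(st.floats(0.0, 359.9), min_size=4, max_size=4),
        speeds=st.lists(st.floats(0.5, 40.0), min_size=4, max_size=4),
        fs=st.lists(st.floats(0.7, 1.3), min_size=4, max_size=4),
        vus=st.lists(st.floats(0.0, 359.9), min_size=4, max_size=4),
        hours=st.floats(0.0, 8000.0),
        z0=st.floats(0.0, 3.0),
    )
    def test_oracle_equivalence_and_amplitude_bound(
        self, amps, phases, speeds, fs, vus, hours, z0
    ):
        n = len(amps)
        cons = tuple(
            Constituent(f"C{i}", amps[i], phases[i], speeds[i]) for i in range(n)
        )
        station = StationHarmonics(
            "prop", "P", z0, 0.0, cons,
            {2013: YearCorrections(2013, tuple(fs[:n]), tuple(vus[:n]))},
        )
        t = datetime(2013, 1, 1) + timedelta(hours=hours)
        h = predict_height(station, t)
        assert h == pytest.approx(direct_sum(station, t), rel=1e-12, abs=1e-12)
        bound = sum(f * c.amplitude for f, c in zip(fs, cons))
        assert abs(h - z0) <= bound + 1e-9

    def test_superposition_of_constituent_sets(self, three_constituent_station):
        full = three_constituent_station
        t = datetime(2013, 3, 5, 7, 11)
        parts = []
        yc = full.year_corrections[2013]
        for i, c in enumerate(full.constituents):
            parts.append(
                StationHarmonics(
                    "part", f"P{i}", full.datum_offset, 0.0, (c,),
                    {2013: YearCorrections(
                        2013, (yc.node_factors[i],), (yc.equilibrium_args[i],)
                    )},
                )
            )
        total = sum(predict_height(p, t) for p in parts)
        expected = total - (len(parts) - 1) * full.datum_offset
        assert predict_height(full, t) == pytest.approx(expected, rel=1e-12)

    def test_periodicity_of_single_constituent(self, m2_station, jan1):
        t = jan1 + timedelta(hours=100.0)
        period = timedelta(hours=360.0 / M2)
        assert predict_height(m2_station, t + period) == pytest.approx(
            predict_height(m2_station, t), abs=1e-9
        )


class TestPredictSeries:
    def test_sample_count_and_pointwise_agreement(self, three_constituent_station):
        start = datetime(2013, 6, 1)
        end = datetime(2013, 6, 2)
        series = predict_series(three_constituent_station, start, end, 600)
        assert len(series) == 86400 // 600 + 1
        for k in (0, 17, len(series) - 1):
            assert series.heights[k] == pytest.approx(
                predict_height(three_constituent_station, series.time_at(k)),
                rel=1e-12,
            )

    def test_full_period_returns_to_start(self, jan1):
        # 30 deg/hr puts the 12 h period exactly on the minute grid
        station = make_single_constituent_station(1.0, 30.0, 40.0, 0.3, 2013)
        series = predict_series(station, jan1, jan1 + timedelta(hours=12), 60)
        assert series.heights[-1] == pytest.approx(series.heights[0], abs=1e-9)

    def test_year_boundary_continuity_within_slew_bound(self):
        station = make_single_constituent_station(
            1.0, M2, 30.0, 0.5, 2013, n_years=2
        )
        series = predict_series(
            station, datetime(2013, 12, 31, 22), datetime(2014, 1, 1, 2), 60
        )
        # max possible step-to-step change: sum_i f_i A_i omega_i * dt (radians)
        bound = 1.0 * M2 * (60 / 3600) * math.pi / 180
        assert np.all(np.abs(np.diff(series.heights)) <= bound + 1e-12)

    def test_year_boundary_without_table_raises(self, m2_station):
        with pytest.raises(UnsupportedYearError, match="2014"):
            predict_series(
                m2_station, datetime(2013, 12, 31), datetime(2014, 1, 2), 60
            )

    def test_reversed_range_rejected(self, m2_station, jan1):
        with pytest.raises(MesotideError, match="after"):
            predict_series(m2_station, jan1, jan1 - timedelta(hours=1), 60)


class TestFindExtrema:
    def test_single_cosine_extrema_match_closed_form(self, m2_station, jan1):
        period_h = 360.0 / M2
        events = find_extrema(m2_station, jan1, jan1 + timedelta(hours=2 * period_h))
        highs = [e for e in events if e.kind == "high"]
        lows = [e for e in events if e.kind == "low"]
        assert highs and lows
        for e in highs:
            tau = (e.time - jan1).total_seconds() / 3600.0
            assert (M2 * tau) % 360.0 == pytest.approx(0.0, abs=0.01) or (
                M2 * tau
            ) % 360.0 == pytest.approx(360.0, abs=0.01)
            assert e.height == pytest.approx(1.0, abs=1e-7)
        for e in lows:
            assert e.height == pytest.approx(-1.0, abs=1e-7)

    def test_events_alternate_kind(self, mixed_station):
        events = find_extrema(
            mixed_station, datetime(2013, 7, 1), datetime(2013, 7, 5)
        )
        assert len(events) >= 6
        for a, b in zip(events, events[1:]):
            assert a.kind != b.kind
            assert a.time < b.time

    def test_two_constituent_events_match_one_second_brute_force(self):
        cons = (
            Constituent("M2", 0.8, 40.0, M2),
            Constituent("K1", 0.4, 310.0, SPEEDS["K1"]),
        )
        station = StationHarmonics(
            "two-term", "T2", 1.0, 0.0, cons,
            {2013: YearCorrections(2013, (1.0, 1.0), (20.0, 200.0))},
        )
        start = datetime(2013, 7, 1)
        end = start + timedelta(hours=48)
        events = find_extrema(station, start, end)
        dense = predict_series(station, start, end, 1.0)  # 1 s brute-force grid
        h = dense.heights
        interior = np.flatnonzero(
            ((h[1:-1] >= h[:-2]) & (h[1:-1] >= h[2:]))
            | ((h[1:-1] <= h[:-2]) & (h[1:-1] <= h[2:]))
        ) + 1
        # collapse plateaus of the dense grid to their first sample
        ref = []
        for idx in interior:
            if ref and idx - ref[-1] <= 2:
                continue
            ref.append(idx)
        assert len(events) == len(ref)
        for ev, idx in zip(events, ref):
            t_ref = start + timedelta(seconds=float(idx))
            assert abs((ev.time - t_ref).total_seconds()) <= 60.0
            assert abs(ev.height - h[idx]) <= 1e-3  # 1 mm

    def test_event_height_bounds_neighboring_grid(self, mixed_station):
        start = datetime(2013, 7, 1)
        events = find_extrema(mixed_station, start, start + timedelta(hours=30))
        grid = predict_series(mixed_station, start, start + timedelta(hours=30), 60)
        for e in events:
            k = int((e.time - start).total_seconds() // 60)
            lo, hi = max(k - 1, 0), min(k + 2, len(grid) - 1)
            neighborhood = grid.heights[lo : hi + 1]
            if e.kind == "high":
                assert e.height >= neighborhood.max() - 1e-9
            else:
                assert e.height <= neighborhood.min() + 1e-9


def test_series_csv_round_trip(tmp_path, three_constituent_station):
    series = predict_series(
        three_constituent_station, datetime(2013, 2, 1), datetime(2013, 2, 2), 60
    )
    p = tmp_path / "series.csv"
    series_to_csv(series, p)
    back = series_from_csv(p)
    assert back.start == series.start
    assert back.step == series.step
    np.testing.assert_allclose(back.heights, series.heights, atol=1e-6)
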