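"""Predict a week of tides for a synthetic mixed-semidiurnal station.

Builds a seeded five-constituent station (M2, S2, K1, O1, SA), synthesizes
a minute-wise height series for one week, and lists the high/low tides.
Heights are meters above MLLW; note the two unequal highs and two unequal
lows per ~24.8 h lunar day — the diurnal inequality of a mixed regime.
"""

from datetime import datetime

from mesotide import find_extrema, make_mixed_semidiurnal_station, predict_series

station = make_mixed_semidiurnal_station(seed=1)
start, end = datetime(2013, 7, 11), datetime(2013, 7, 18)

series = predict_series(station, start, end, step=60)
print(f"{station.station_name}: {len(series)} minute samples")
print(f"height range {series.heights.min():.3f} .. {series.heights.max():.3f} m above MLLW")

print("\nhigh/low tides:")
for ev in find_extrema(station, start, end):
    print(f"  {ev.time}  {ev.height:6.3f} m  {ev.kind}")
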