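# Station file schema

A station harmonics file is a single JSON object. Example files ship in
`data/stations/` (both synthetic, generated by `mesotide.fixtures`).

```json
{
  "station_name": "synthetic mixed semidiurnal (seed 1)",
  "station_id": "SYN-MIXED-1",
  "units": "m",
  "datum_offset": 0.87,
  "utc_offset_hours": -8.0,
  "constituents": [
    {"name": "M2", "amplitude": 0.55, "phase_lag": 131.2, "speed": 28.9841042}
  ],
  "years": {
    "2013": {"node_factors": [1.0], "equilibrium_args": [42.0]}
  }
}
```

| key | meaning |
| --- | --- |
| `station_name` | free text |
| `station_id` | external identifier (e.g. a NOAA station id) |
| `units` | `"m"` or `"ft"`; feet are converted to meters once on load (amplitudes and `datum_offset` only) |
| `datum_offset` | Z0, height of mean water level above MLLW (≥ 0) |
| `utc_offset_hours` | local standard time offset; metadata only — all arithmetic is in local standard time |
| `constituents` | ordered array of `{name, amplitude, phase_lag, speed}`; amplitude ≥ 0 (m), phase lag in [0, 360) deg, speed > 0 deg/hr; names unique; **order is semantic** — year tables align by index |
| `years` | map of calendar year → `{node_factors, equilibrium_args}`; both arrays exactly as long as `constituents`; node factors > 0; equilibrium arguments in degrees, referenced to **local standard midnight of Jan 1** of that year |

No extra keys are allowed; missing or unknown fields, non-finite numbers,
and misaligned year tables are rejected with errors naming the offending
field or year. `save_station` always writes meters and round-trips
bit-for-bit through `load_station`.
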