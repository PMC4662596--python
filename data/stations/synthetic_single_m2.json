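{
  "station_name": "synthetic single-constituent",
  "station_id": "SYN-1",
  "units": "m",
  "datum_offset": 0.0,
  "utc_offset_hours": -8.0,
  "constituents": [
    {
      "name": "SYN",
      "amplitude": 1.0,
      "phase_lag": 0.0,
      "speed": 28.9841042
    }
  ],
  "years": {
    "2013": {
      "node_factors": [
        1.0
      ],
      "equilibrium_args": [
        0.0
      ]
    }
  }
}
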