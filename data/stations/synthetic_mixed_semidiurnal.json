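{
  "station_name": "synthetic mixed semidiurnal (seed 1)",
  "station_id": "SYN-MIXED-1",
  "units": "m",
  "datum_offset": 0.87,
  "utc_offset_hours": -8.0,
  "constituents": [
    {
      "name": "M2",
      "amplitude": 0.5523643249400514,
      "phase_lag": 342.1669306773367,
      "speed": 28.9841042
    },
    {
      "name": "S2",
      "amplitude": 0.16874074965355237,
      "phase_lag": 341.5138009694078,
      "speed": 30.0
    },
    {
      "name": "K1",
      "amplitude": 0.29677471780157283,
      "phase_lag": 152.39752163012724,
      "speed": 15.0410686
    },
    {
      "name": "O1",
      "amplitude": 0.23277025938204418,
      "phase_lag": 147.31168909289806,
      "speed": 13.9430356
    },
    {
      "name": "SA",
      "amplitude": 0.057479684383652974,
      "phase_lag": 9.921280767504612,
      "speed": 0.0410686
    }
  ],
  "years": {
    "2013": {
      "node_factors": [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      "equilibrium_args": [
        271.2647191229304,
        193.73159275894017,
        118.70341793967317,
        283.83433323422554,
        109.15013854499219
      ]
    },
    "2014": {
      "node_factors": [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      "equilibrium_args": [
        12.017511122947326,
        193.73159275896614,
        118.46435393969296,
        24.826189234212507,
        108.91107454499218
      ]
    }
  }
}
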