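"""Simulate the tide-height-control rack over a spring-tide stretch.

The rack carriage (and hence the aquarium water level) tracks the predicted
tide in 12.7 um stepper increments but cannot leave its travel window; when
the natural tide exceeds a limit the carriage parks there until the tide
returns.  The printed min/max show the realized water level saturating at
the window edges while the free tide overshoots them.
"""

from datetime import datetime

from mesotide import RackConfig, make_mixed_semidiurnal_station, predict_series, simulate_rack

station = make_mixed_semidiurnal_station(seed=1)
tide = predict_series(station, datetime(2013, 7, 11), datetime(2013, 7, 25), step=60)

# place the travel window inside the tide's excursion so both limits engage
upper = tide.heights.max() - 0.15
config = RackConfig(upper_limit=upper, travel=upper - (tide.heights.min() + 0.15))

water, steps = simulate_rack(tide, config, return_steps=True)
print(f"free tide:   {tide.heights.min():.3f} .. {tide.heights.max():.3f} m")
print(f"rack window: {config.lower_limit:.3f} .. {config.upper_limit:.3f} m")
print(f"water level: {water.heights.min():.3f} .. {water.heights.max():.3f} m")
print(f"largest single-minute move: {abs(steps).max()} steps "
      f"({abs(steps).max() * config.step_size * 1000:.2f} mm)")
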