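# Methods

## The model

`mesotide` re-creates, at desk scale, a laboratory tide-height-control (THC)
system: a microcontroller that predicts the local tide every minute and
drives a stepper-motor lead-screw rack whose carriage height sets the drain
height — and therefore the water level — of connected mesocosm aquaria.
The package has four computational layers:

1. **Harmonic synthesis.** Tide height above the MLLW datum is the
   classical harmonic sum

   ```
   h(t) = Z0 + Σ_i f_i · A_i · cos( ω_i·τ + (V0+u)_i − κ_i )
   ```

   where, per constituent *i*, `A_i` is the amplitude (m), `κ_i` the phase
   lag (deg), `ω_i` the angular speed (deg/hr), `f_i` the node factor and
   `(V0+u)_i` the equilibrium argument (deg). `Z0` is the height of mean
   water level above MLLW (m). `τ` is fractional hours elapsed since
   local-standard midnight of Jan 1 of the prediction year — the epoch the
   per-year `f` and `(V0+u)` tables are referenced to. Angles stay in
   degrees end-to-end and are converted to radians only inside the cosine.

2. **Extrema detection.** High/low tides are located from sign changes of
   the first difference on a 1-minute grid and refined on the analytic
   derivative (Brent root-finding, with a bounded golden-section fallback
   when the derivative does not bracket) to 1 s. Ties in flat stretches
   resolve to the earliest time; consecutive same-kind candidates collapse
   to the more extreme one so returned events always alternate.

3. **Rack simulation.** Each update interval (default 60 s, the
   controller's cadence) the predicted height is clamped into the travel
   window `[upper_limit − travel, upper_limit]` and the move to that target
   is quantized to whole motor steps (`step_size = screw_pitch /
   steps_per_rev`; defaults 2.54 mm — 0.1 in — per revolution and
   200 steps/rev, i.e. 12.7 µm/step). Sub-step remainders carry forward as
   a residual, so commanded travel never drifts more than one step from
   requested travel. Water level equals carriage height (ideal
   equalization); an optional first-order lag (`lag_tau`, seconds, off by
   default) models hose hydraulics for realism studies.

4. **Submergence accounting.** A sample is *submerged* at elevation `e`
   when `height ≥ e` — water exactly at soil height counts; the tie-break
   is fixed and tested. Each sample represents one sampling interval, so
   submerged time is `count · step`. "Days with an event" are local
   calendar days (midnight boundaries) containing ≥ 1 submerged sample.
   Displayed hours round half-up to integers; percent of record is computed
   from *unrounded* hours and then rounded to one decimal. The same
   per-sample classification yields alternating above/below actuation
   intervals (for valve or spray control) whose above-durations equal the
   report's submerged seconds exactly.

## Conventions and assumptions

- **Time.** All timestamps are naive local standard time; the controller's
  clock runs standard time year-round, so there is no daylight-saving
  handling anywhere. `utc_offset_hours` in the station file is metadata
  only.
- **Yearly correction tables.** `f` and `(V0+u)` are constants for a whole
  calendar year, tabulated per year in the station file; the package does
  not compute them from lunar/solar orbital elements (Schureman formulae) —
  tables are inputs. The error of year-constant node factors is small over
  one year. Equilibrium arguments in the native format are referenced to
  local standard midnight of Jan 1; a supplier whose tables use a different
  epoch must convert before writing the file.
- **Units.** Meters internally; a station file may declare `"units":
  "ft"`, converted once on load (amplitudes and datum only — phases and
  speeds are angles/rates).
- **Travel limits.** The commanded step count is truncated whenever the
  nearest-step move would overrun a travel limit, and the residual is
  re-referenced to zero — the software analogue of halting on a limit
  switch. Without this, nearest rounding could overshoot a limit by half a
  step and the residual could grow without bound while the tide sits
  beyond the window. A final epsilon clamp guards the accumulated
  `carriage + k·step` float error (~1e-14 m) so containment is exact.
- **Restart behavior.** The simulator keeps no persistent state beyond the
  configuration: a simulation restarted at any timestamp re-clamps its
  first sample immediately, mirroring the hardware's battery-backed-clock
  reboot behavior.

## Numerical choices

- Extrema refinement tolerance: 1 s in time (`xtol`), far below the
  1-minute actuation cadence; event heights are re-evaluated analytically
  at the refined (whole-second) time.
- Step rounding: nearest, ties away from zero; residual stays in
  (−step_size, step_size).
- Half-up rounding for displayed hours and for the 1-decimal percent
  (avoids banker's rounding surprises in tabulated summaries).
- `predict_series` sample count is `floor((end−start)/step) + 1` with a
  1 ns guard against float division landing just below an integer.
- Series spanning multiple calendar years are synthesized per year segment
  with that year's table and epoch; tables whose equilibrium arguments
  advance coherently across Jan 1 (as the synthetic generator builds them)
  produce no artificial jump at the boundary.

## The synthetic-data generator

`make_mixed_semidiurnal_station(seed)` emulates a mixed semidiurnal regime:
five constituents — M2, S2 (semidiurnal), K1, O1 (diurnal), SA
(long-period) — at their standard published speeds, with amplitudes drawn
per seed from ranges typical of a southern California estuary station
(M2 0.45–0.65 m, S2 0.15–0.28 m, K1 0.25–0.40 m, O1 0.15–0.25 m,
SA 0.03–0.08 m) over a 0.87 m datum offset, and uniform random phases.
Node factors are 1 and equilibrium arguments are seeded, with multi-year
tables built to be continuous across year boundaries. This reproduces the
*structure* real stations exhibit — diurnal inequality (two unequal highs
and lows per 24.84 h lunar day), spring/neap beating, a realistic ~2 m
excursion — but not any specific station's constituent set (37+
constituents at a real NOAA station), its shallow-water overtides, or
meteorological residuals. Passing tests on these fixtures therefore
demonstrate correctness of the synthesis/controller/accounting machinery,
not agreement with any particular harbor; agreement with a real station
requires its published constituents and real yearly corrections via the
station file (the `fetch-station` helper retrieves constituents where the
network allows; yearly corrections must come from an external table).

`make_square_wave_series` provides exactly countable submergence oracles;
`make_single_constituent_station` provides closed-form oracles
(`Z0 + A·cos(ωτ − κ)`).

## Problem sizes

The test suite and the acceptance script run at desk scale: minute-wise
series of 2–60 days, 1-second brute-force grids over 48 h windows,
10,000-move quantization drift accumulations, and 500-point oracle probes —
sizes at which every oracle can be enumerated exactly while still
exercising spring/neap structure and both travel limits.

## Known limitations

- Node factors and equilibrium arguments are inputs; no astronomical
  ephemeris is computed.
- Hose/siphon hydraulics are reduced to ideal equalization (optionally a
  single first-order lag); motor torque and acceleration are not modeled.
- Datum handling is limited to the stored MLLW offset; no other datum
  conversions.
- The 1-minute candidate grid in `find_extrema` can merge extrema closer
  than ~2 minutes apart; for ordinary tidal signals this never occurs.
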