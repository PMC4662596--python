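"""Tide-height-control (THC) rack simulation.

The physical system is a stepper-motor-driven lead screw that raises and
lowers a carriage inside a rack frame; aquarium drain hoses terminate at
the carriage, so the water level in each tank equalizes with the carriage
height (ideal equalization is the default model; an optional first-order
lag is available for hydraulics realism studies).

Every update interval (60 s by default) the controller clamps the predicted
tide to the travel window ``[upper_limit - travel, upper_limit]`` and
commands an integer number of motor steps toward that target.  When the
natural tide exceeds a travel limit the carriage halts at the limit until
the tide re-enters the window.  Sub-step position error is carried forward
as a residual so quantization never accumulates into drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import TideSeries
from .errors import MesotideError

INCH = 0.0254


@dataclass(frozen=True)
class RackConfig:
    """Travel window and screw geometry.

    Defaults: 0.1 in (2.54 mm) screw pitch and a 200 step/rev stepper,
    giving a 12.7 um position quantum.
    """

    upper_limit: float
    travel: float
    screw_pitch: float = 0.1 * INCH
    steps_per_rev: int = 200
    update_interval: float = 60.0

    def __post_init__(self):
        if self.travel <= 0:
            raise MesotideError(f"travel must be > 0, got {self.travel}")
        if self.screw_pitch <= 0:
            raise MesotideError(f"screw_pitch must be > 0, got {self.screw_pitch}")
        if self.steps_per_rev <= 0:
            raise MesotideError(f"steps_per_rev must be > 0, got {self.steps_per_rev}")
        if self.update_interval <= 0:
            raise MesotideError(
                f"update_interval must be > 0, got {self.update_interval}"
            )

    @property
    def lower_limit(self) -> float:
        return self.upper_limit - self.travel

    @property
    def step_size(self) -> float:
        """Meters of carriage travel per motor step."""
        return self.screw_pitch / self.steps_per_rev


@dataclass(frozen=True)
class RackState:
    """Carriage height (m above MLLW) and sub-step position residual (m)."""

    carriage_height: float
    step_residual: float = 0.0


def target_position(h: float, config: RackConfig) -> float:
    """Clamp a predicted tide height into the rack's travel window."""
    return min(max(h, config.lower_limit), config.upper_limit)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def steps_for_move(
    delta: float, state: RackState, config: RackConfig
) -> tuple[int, RackState]:
    """Quantize a requested carriage move into whole motor steps.

    The commanded step count is ``round((delta + residual) / step_size)``
    to nearest, ties away from zero; the leftover sub-step distance becomes
    the new residual, so the accumulated commanded travel never drifts more
    than one step from the accumulated requests.
    """
    s = config.step_size
    want = delta + state.step_residual
    steps = _round_half_away(want / s)
    new_state = RackState(
        carriage_height=state.carriage_height + steps * s,
        step_residual=want - steps * s,
    )
    return steps, new_state


def _limit_steps(steps: int, carriage: float, config: RackConfig) -> int:
    """Clamp a commanded step count so the carriage stays inside the travel window."""
    s = config.step_size
    max_up = math.floor((config.upper_limit - carriage) / s + 1e-9)
    max_down = math.floor((carriage - config.lower_limit) / s + 1e-9)
    return min(max(steps, -max_down), max_up)


def simulate_rack(
    series: TideSeries,
    config: RackConfig,
    *,
    lag_tau: float | None = None,
    return_steps: bool = False,
):
    """Run the controller over a predicted tide series.

    Returns the realized water-level series (water level == carriage
    height under ideal equalization).  The initial carriage sits at the
    clamped first sample; thereafter each update commands the quantized
    step move toward the clamped target.  If the nearest-step command
    would overrun a travel limit it is truncated at the limit and the
    residual is re-referenced to zero — the software analogue of halting
    on a limit switch.

    ``lag_tau`` (seconds), if given, applies a first-order equalization
    lag to the water level: ``w += (c - w) * (1 - exp(-dt/tau))``.

    With ``return_steps=True`` also returns the per-update commanded step
    counts (length ``len(series)``; the first entry is 0).
    """
    if not math.isclose(series.step, config.update_interval):
        raise MesotideError(
            f"series step ({series.step} s) must equal the rack update "
            f"interval ({config.update_interval} s)"
        )
    s = config.step_size
    carriage = target_position(float(series.heights[0]), config)
    state = RackState(carriage_height=carriage)
    out = np.empty(len(series))
    steps_log = np.zeros(len(series), dtype=int)
    out[0] = carriage
    for k in range(1, len(series)):
        target = target_position(float(series.heights[k]), config)
        steps, state = steps_for_move(target - state.carriage_height, state, config)
        limited = _limit_steps(steps, carriage, config)
        if limited != steps:
            state = RackState(
                carriage_height=carriage + limited * s, step_residual=0.0
            )
            steps = limited
        # float-epsilon guard: accumulated carriage+k*s rounding must never
        # leave the physical window
        clamped = target_position(state.carriage_height, config)
        if clamped != state.carriage_height:
            state = replace(state, carriage_height=clamped)
        carriage = state.carriage_height
        out[k] = carriage
        steps_log[k] = steps
    if lag_tau is not None:
        alpha = 1.0 - math.exp(-series.step / lag_tau)
        w = out[0]
        lagged = np.empty_like(out)
        lagged[0] = w
        for k in range(1, out.size):
            w += (out[k] - w) * alpha
            lagged[k] = w
        out = lagged
    result = TideSeries(start=series.start, step=series.step, heights=out)
    if return_steps:
        return result, steps_log
    return result


def step_log_to_csv(series: TideSeries, steps: np.ndarray, path) -> None:
    """Write the per-update step log: `timestamp,steps,carriage_height_m`."""
    df = pd.DataFrame(
        {
            "timestamp": [t.isoformat() for t in series.times().to_pydatetime()],
            "steps": steps,
            "carriage_height_m": np.round(series.heights, 6),
        }
    )
    df.to_csv(path, index=False)
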