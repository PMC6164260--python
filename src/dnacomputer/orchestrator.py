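"""Chaining the molecular stages into full operating cycles.

One operating cycle runs the stages in fixed order: electronic pulse pair
-> pH/activity trajectory -> catalytic amplification -> thresholding ->
logic gates -> finite-state-machine transition.  Between cycles the
solution is flushed, so no solution-phase species survives a cycle
boundary; the only persistent quantity is the surface-immobilized FSM
state vector.

Two modes are supported.  ``ideal_ob`` injects a stipulated amplifier
output concentration directly at the thresholder boundary — the exact-OB
convention of the reference four-cycle scenario — while ``full_chemistry``
derives the output from a pulse schedule through the amplification stage,
demonstrating the whole chain (its absolute numbers depend on the
configured amplifier rate constants).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import catalytic, fsm, gates, thresholder
from .electrochemistry import (
    ElectrochemicalParams,
    PulseSchedule,
    SwitchModel,
    build_activity_trajectory,
)
from .maze import MazeWorld

__all__ = [
    "InputEncoding",
    "CycleConfig",
    "CycleRecord",
    "ScenarioResult",
    "run_cycle",
    "run_table3_scenario",
    "encode_sensors",
    "run_maze",
    "MazeTrajectory",
    "calibrate_topen",
]


@dataclass(frozen=True)
class InputEncoding:
    """Lookup from electronic input index (1–4) to the molecular encoding.

    ``ob_lookup`` holds the nominal amplifier output per input (molar),
    used directly in ``ideal_ob`` mode.  ``topen_lookup`` holds pulse
    separations (seconds) for ``full_chemistry`` mode; only input 1's
    delay (about one minute) is fixed by design, the rest are calibrated
    at run time by inverting the t_open response
    (:func:`calibrate_topen`).
    """

    ob_lookup: dict = field(
        default_factory=lambda: {1: 1.5e-9, 2: 2.8e-9, 3: 3.9e-9, 4: 5.0e-9}
    )
    topen_lookup: dict = field(default_factory=lambda: {1: 60.0})

    def __post_init__(self) -> None:
        obs = [self.ob_lookup[i] for i in sorted(self.ob_lookup)]
        if sorted(obs) != obs:
            raise ValueError("ob_lookup must be monotone in the input index")
        tops = [self.topen_lookup[i] for i in sorted(self.topen_lookup)]
        if sorted(tops) != tops:
            raise ValueError("topen_lookup must be monotone in the input index")


@dataclass(frozen=True)
class CycleConfig:
    """All per-stage parameters for one operating cycle.

    ``mode`` selects how the amplifier output is obtained (see module
    docstring).  The stage grids default to the published conventions:
    amplification 150000 x 0.05 s (125 min), thresholder endpoint 6000 s,
    gates endpoint 15000 s, FSM settling over a 10 h cycle.
    """

    mode: str = "ideal_ob"
    electro: ElectrochemicalParams = field(default_factory=ElectrochemicalParams)
    switch: SwitchModel = field(default_factory=lambda: SwitchModel(total_switch=1.7e-9))
    cycle_init: catalytic.CycleInitialState = field(
        default_factory=catalytic.CycleInitialState
    )
    cycle_rates: catalytic.CycleRates = field(default_factory=catalytic.CycleRates)
    thresh_params: thresholder.ThresholderParams = field(
        default_factory=thresholder.ThresholderParams
    )
    gate_params: gates.GateParams = field(default_factory=gates.GateParams)
    fsm_params: fsm.FsmDynamicsParams = field(default_factory=fsm.FsmDynamicsParams)
    tensor: np.ndarray = field(default_factory=fsm.build_left_wall_tensor)
    encoding: InputEncoding = field(default_factory=InputEncoding)
    dt: float = 0.05
    cycle_n_steps: int = 150_000
    thresh_duration: float = thresholder.DEFAULT_DURATION
    gate_duration: float = gates.DEFAULT_DURATION

    def __post_init__(self) -> None:
        if self.mode not in ("ideal_ob", "full_chemistry"):
            raise ValueError("mode must be 'ideal_ob' or 'full_chemistry'")

    def coarse(self, factor: int = 10) -> "CycleConfig":
        """A cheaper configuration with the step size scaled up by ``factor``.

        Keeps every physical duration unchanged; useful for quick runs
        where the 0.05 s convention is unnecessarily fine.
        """
        return replace(self, dt=self.dt * factor,
                       cycle_n_steps=self.cycle_n_steps // factor)


@dataclass(frozen=True)
class CycleRecord:
    """Everything recorded for one operating cycle."""

    input_index: int
    ob_final: float                       # molar
    thresholder_endpoint: np.ndarray      # molar, (4,)
    active_gates: np.ndarray              # molar, (4,)
    winner: gates.GateWinner
    s_initial: np.ndarray
    s_final: np.ndarray
    t_open: Optional[float] = None        # seconds, full_chemistry mode only

    @property
    def desired_occupancy(self) -> float:
        """Fraction of the ensemble in the intended (dominant) final state."""
        return float(np.max(self.s_final))

    def to_dict(self) -> dict:
        return {
            "input_index": self.input_index,
            "t_open_s": self.t_open,
            "ob_final_nM": self.ob_final * 1e9,
            "thresholder_nM": (self.thresholder_endpoint * 1e9).tolist(),
            "active_gates_pM": (self.active_gates * 1e12).tolist(),
            "winner_gate": self.winner.gate,
            "initial_state": self.s_initial.tolist(),
            "final_state": self.s_final.tolist(),
        }


class StageError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _amplifier_output(config: CycleConfig, input_index: int) -> tuple[float, Optional[float]]:
    if config.mode == "ideal_ob":
        return config.encoding.ob_lookup[input_index], None
    t_open = config.encoding.topen_lookup.get(input_index)
    if t_open is None:
        raise KeyError(
            f"no t_open configured for input {input_index}; "
            "run calibrate_topen first"
        )
    grid = np.arange(config.cycle_n_steps) * config.dt
    activity = build_activity_trajectory(
        PulseSchedule(0.0, t_open), config.electro, config.switch, time_grid=grid
    )
    result = catalytic.simulate_cycle(config.cycle_init, config.cycle_rates, activity)
    return result.ob_final, t_open


def run_cycle(config: CycleConfig, input_index: int, s_prev) -> CycleRecord:
    """Execute one full operating cycle from a fresh (post-flush) state."""
    if input_index not in (1, 2, 3, 4):
        raise ValueError("input_index must be 1..4")
    s_prev = fsm.normalize(s_prev)
    try:
        ob_final, t_open = _amplifier_output(config, input_index)
    except Exception as err:
        raise StageError("catalytic_cycle", err) from err
    try:
        thr = thresholder.simulate_thresholder(
            ob_final, config.thresh_params, dt=config.dt,
            duration=config.thresh_duration,
        )
    except Exception as err:
        raise StageError("thresholder", err) from err
    try:
        gate_res = gates.simulate_gates(
            thr.free_endpoint, config.gate_params, dt=config.dt,
            duration=config.gate_duration,
        )
    except Exception as err:
        raise StageError("logic_gates", err) from err
    try:
        s_final = fsm.fsm_transition(s_prev, gate_res.active_endpoint, config.tensor)
    except Exception as err:
        raise StageError("fsm", err) from err
    return CycleRecord(
        input_index=input_index,
        ob_final=ob_final,
        thresholder_endpoint=thr.free_endpoint,
        active_gates=gate_res.active_endpoint,
        winner=gates.winner(gate_res.active_endpoint),
        s_initial=s_prev,
        s_final=s_final,
        t_open=t_open,
    )


@dataclass(frozen=True)
class ScenarioResult:
    """Chained multi-cycle run with per-cycle records and flush boundaries."""

    records: list
    fsm_params: fsm.FsmDynamicsParams

    def min_desired_occupancy(self) -> float:
        """Smallest end-of-cycle occupancy of the intended state.

        Evaluated after single-exponential settling over the full cycle
        duration; the occupancy of a state is the corresponding element of
        the (unit-norm) state vector.
        """
        occ = []
        for rec in self.records:
            settled = fsm.fsm_dynamics(
                rec.s_initial, rec.s_final, self.fsm_params,
                self.fsm_params.settle_time,
            )
            occ.append(float(settled[int(np.argmax(rec.s_final))]))
        return min(occ)

    def state_blocks(self) -> pd.DataFrame:
        """Block-raster time series of state occupancies, one row per block.

        Samples the settling dynamics every ``block_interval`` seconds
        through each cycle (columns P_F, P_L, P_R).
        """
        rows = []
        p = self.fsm_params
        for k, rec in enumerate(self.records):
            times = np.arange(0.0, p.settle_time, p.block_interval)
            states = fsm.fsm_dynamics(rec.s_initial, rec.s_final, p, times)
            for t, s in zip(times, states):
                rows.append({
                    "time_s": k * p.settle_time + t, "cycle": k + 1,
                    "P_F": s[0], "P_L": s[1], "P_R": s[2],
                })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "cycles": [rec.to_dict() for rec in self.records],
            "min_desired_occupancy": self.min_desired_occupancy(),
        }


def run_table3_scenario(
    config: CycleConfig | None = None,
    input_sequence=(1, 2, 3, 4),
    s0=(1.0, 0.0, 0.0),
) -> ScenarioResult:
    """Run the reference four-cycle scenario.

    Starting from a homogeneous ensemble in state F, the electronic inputs
    1–4 arrive in successive cycles (nominal amplifier outputs 1.5, 2.8,
    3.9 and 5.0 nM in ``ideal_ob`` mode); each cycle starts from the final
    state of the previous one, with a flush in between.
    """
    config = config or CycleConfig()
    records = []
    s = fsm.normalize(s0)
    for idx in input_sequence:
        rec = run_cycle(config, idx, s)
        records.append(rec)
        s = rec.s_final
    return ScenarioResult(records=records, fsm_params=config.fsm_params)


def encode_sensors(world: MazeWorld, s_prev) -> int:
    """Priority encoding of the sensor pair into the electronic input index.

    A wall ahead always wins (input 1).  Otherwise a machine dominantly in
    state R reports the cleared forward sensor (input 2); otherwise the
    left sensor decides: clear left means input 3, wall on the left means
    input 4.  Exactly one input is true by construction, matching the
    defined transitions of the left-wall follower.
    """
    s_prev = np.asarray(s_prev, dtype=float)
    dominant = fsm.STATE_LABELS[int(np.argmax(s_prev))]
    if world.sensor_forward:
        return 1
    if dominant == "R":
        return 2
    if not world.sensor_left:
        return 3
    return 4


@dataclass(frozen=True)
class MazeTrajectory:
    """Pose history of a maze run plus the underlying cycle records."""

    poses: list               # (row, col, heading) after each cycle
    scenario: ScenarioResult
    reached_exit: bool
    exhausted: bool           # stopped because max_cycles ran out


def run_maze(
    config: CycleConfig,
    world: MazeWorld,
    max_cycles: int = 50,
    s0=(1.0, 0.0, 0.0),
) -> MazeTrajectory:
    """Drive the robot through the maze, one operating cycle per action.

    Each cycle: read the sensors, encode them as an electronic input, run
    the molecular pipeline, then act on the dominant final state (F:
    advance one cell; R/L: rotate 90 degrees, consuming the cycle).  Stops
    at an exit cell or after ``max_cycles``.
    """
    records = []
    poses = [world.pose]
    s = fsm.normalize(s0)
    reached = world.at_exit
    cycles = 0
    while not reached and cycles < max_cycles:
        idx = encode_sensors(world, s)
        rec = run_cycle(config, idx, s)
        records.append(rec)
        s = rec.s_final
        dominant = fsm.STATE_LABELS[int(np.argmax(s))]
        if dominant == "F":
            world.advance()
        else:
            world.rotate(dominant)
        poses.append(world.pose)
        reached = world.at_exit
        cycles += 1
    return MazeTrajectory(
        poses=poses,
        scenario=ScenarioResult(records=records, fsm_params=config.fsm_params),
        reached_exit=reached,
        exhausted=not reached,
    )


def calibrate_topen(
    config: CycleConfig,
    inputs=(2, 3, 4),
    tol: float = 0.02e-9,
    max_iter: int = 30,
) -> InputEncoding:
    """Invert the t_open response to fill the pulse-delay lookup table.

    For each requested input index, bisects t_open until the simulated
    amplifier output matches the nominal output of ``ob_lookup`` to within
    ``tol`` (molar), within the reaction window.  Returns a new encoding
    with the calibrated delays merged in.
    """
    topen = dict(config.encoding.topen_lookup)
    window = config.cycle_n_steps * config.dt
    hi_limit = window - config.electro.pulse_duration - 1.0

    def ob_at(t_open: float) -> float:
        table = catalytic.ob_final_vs_topen(
            config.cycle_init, config.cycle_rates, config.electro, config.switch,
            [t_open], dt=config.dt, n_steps=config.cycle_n_steps,
        )
        return float(table.ob_final_M.iloc[0])

    for idx in inputs:
        target = config.encoding.ob_lookup[idx]
        lo, hi = config.electro.pulse_duration, hi_limit
        if ob_at(hi) < target:
            raise ValueError(
                f"target output {target:.2e} M for input {idx} is unreachable "
                "within the reaction window"
            )
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            ob = ob_at(mid)
            if abs(ob - target) < tol:
                break
            if ob < target:
                lo = mid
            else:
                hi = mid
        topen[idx] = mid
    return replace(config.encoding, topen_lookup=topen)
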