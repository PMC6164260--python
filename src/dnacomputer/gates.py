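"""Dumb-bell hairpin logic gates reading the thresholder's band code.

Each gate is a two-hairpin (dumb-bell) construct: one reporter species
opens the first stem and activates the gate, the next reporter in the
series opens the second stem, whose loop is the reverse complement of the
first, locking the gate shut (deactivation).  With reporters A–D produced
by the thresholder, gate m is activated by reporter m and deactivated by
reporter m+1; gate 4 has no deactivator.  Exactly one gate then ends
strongly active, identifying which concentration band the amplifier output
fell in:

    gate 1:  A and not B      gate 3:  C and not D
    gate 2:  B and not C      gate 4:  D

All seven reactions are irreversible and bimolecular; note that reporters
B, C and D each feed two sinks (activation of their own gate and
deactivation of the previous one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._integrate import euler, recorded_times
from .thresholder import CHANNELS

#: Endpoint convention (seconds) reproducing the published operating table;
#: see docs/methods.md.
DEFAULT_DURATION = 15_000.0
DEFAULT_DT = 0.05

__all__ = [
    "GateParams",
    "GateResult",
    "GateWinner",
    "simulate_gates",
    "winner",
]


@dataclass(frozen=True)
class GateParams:
    """Rate constants and totals for gates G1–G4 (SI units).

    ``k_act[m]`` is the activation rate of gate m+1 by its reporter;
    ``k_deact[m]`` the deactivation rate of gate m+1 by the next reporter
    (gate 4 is never deactivated).  Defaults follow published
    strand-displacement rates: 6e6 /M/s for gates 1–2 (activation and
    deactivation), 2.5e6 /M/s for gate 3, and a slow 2.5e5 /M/s activation
    for gate 4.
    """

    k_act: np.ndarray = field(
        default_factory=lambda: np.array([6e6, 6e6, 2.5e6, 2.5e5])
    )
    k_deact: np.ndarray = field(
        default_factory=lambda: np.array([6e6, 6e6, 2.5e6])
    )
    gate_tot: np.ndarray = field(default=0.1e-9)

    def __post_init__(self) -> None:
        k_act = np.asarray(self.k_act, dtype=float)
        k_deact = np.asarray(self.k_deact, dtype=float)
        gate_tot = np.broadcast_to(np.asarray(self.gate_tot, dtype=float), (4,)).copy()
        if k_act.shape != (4,) or np.any(k_act < 0):
            raise ValueError("k_act must be 4 non-negative rates")
        if k_deact.shape != (3,) or np.any(k_deact < 0):
            raise ValueError("k_deact must be 3 non-negative rates")
        if np.any(gate_tot < 0):
            raise ValueError("gate_tot must be non-negative")
        object.__setattr__(self, "k_act", k_act)
        object.__setattr__(self, "k_deact", k_deact)
        object.__setattr__(self, "gate_tot", gate_tot)


@dataclass(frozen=True)
class GateResult:
    """Trajectories of the free reporters and the gate pools."""

    time: np.ndarray
    inputs: np.ndarray      # (n, 4) free reporters A-D
    unreacted: np.ndarray   # (n, 4)
    active: np.ndarray      # (n, 4)
    inactive: np.ndarray    # (n, 4)
    stationarity: float     # max |d active/dt| at the endpoint, molar/s

    @property
    def active_endpoint(self) -> np.ndarray:
        return self.active[-1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"time_s": self.time})
        for m, ch in enumerate(CHANNELS):
            frame[ch] = self.inputs[:, m]
        for m in range(4):
            frame[f"G{m + 1}_unreacted"] = self.unreacted[:, m]
            frame[f"G{m + 1}_active"] = self.active[:, m]
            frame[f"G{m + 1}_inactive"] = self.inactive[:, m]
        return frame

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def endpoint_summary(self) -> dict:
        return {
            "active_pM": (self.active_endpoint * 1e12).tolist(),
            "stationarity_M_per_s": self.stationarity,
        }


def _gate_rates(y: np.ndarray, params: GateParams):
    inp = y[..., 0:4]
    unreacted = y[..., 4:8]
    active = y[..., 8:12]
    act = params.k_act * unreacted * inp
    deact = params.k_deact * active[..., 0:3] * inp[..., 1:4]
    return act, deact


def simulate_gates(
    initial_inputs,
    params: GateParams | None = None,
    dt: float = DEFAULT_DT,
    duration: float = DEFAULT_DURATION,
    record_every: int = 200,
) -> GateResult:
    """Integrate the gate network from the thresholder's endpoint.

    ``initial_inputs`` are the free reporter concentrations (A, B, C, D) in
    molar.  The state is the four reporters plus the unreacted, active and
    inactive pool of each gate; per-gate conservation
    (unreacted + active + inactive = gate_tot) is preserved by
    construction.  The default endpoint of 15000 s is the convention that
    reproduces the published operating table; the returned ``stationarity``
    diagnostic reports how settled the active pools are at that point.
    """
    params = params or GateParams()
    inp0 = np.asarray(initial_inputs, dtype=float)
    if inp0.shape != (4,):
        raise ValueError("initial_inputs must be the four reporter concentrations")
    if np.any(inp0 < 0):
        raise ValueError("initial_inputs must be non-negative")
    n_steps = int(round(duration / dt))

    def rhs(i: int, y: np.ndarray) -> np.ndarray:
        act, deact = _gate_rates(y, params)
        deact4 = np.concatenate(
            [deact, np.zeros(deact.shape[:-1] + (1,))], axis=-1
        )
        # reporter m is consumed by activating gate m and deactivating gate m-1
        d_inp = -act.copy()
        d_inp[..., 1:4] -= deact
        return np.concatenate([d_inp, -act, act - deact4, deact4], axis=-1)

    y0 = np.concatenate([inp0, params.gate_tot, np.zeros(4), np.zeros(4)])
    y_end, traj = euler(rhs, y0, dt, n_steps, record_every=record_every)
    times = recorded_times(dt, n_steps, record_every)
    act_end, deact_end = _gate_rates(y_end, params)
    d_active = act_end - np.concatenate([deact_end, [0.0]])
    return GateResult(
        time=times,
        inputs=traj[:, 0:4],
        unreacted=traj[:, 4:8],
        active=traj[:, 8:12],
        inactive=traj[:, 12:16],
        stationarity=float(np.max(np.abs(d_active))),
    )


@dataclass(frozen=True)
class GateWinner:
    """Identity of the dominant active gate at the endpoint.

    ``gate`` is the 1-based gate number, or ``None`` when no gate is active
    (an all-zero endpoint is a valid "no winner" outcome, not an error).
    ``margin`` is the ratio of the largest to the second-largest active
    concentration (``inf`` if only one gate is active at all).
    """

    gate: Optional[int]
    margin: Optional[float]


def winner(active_endpoint, zero_tol: float = 1e-18) -> GateWinner:
    """Dominant gate and its margin from an endpoint active-concentration vector."""
    active = np.asarray(active_endpoint, dtype=float)
    if active.shape != (4,):
        raise ValueError("expected four active-gate concentrations")
    if np.all(active <= zero_tol):
        return GateWinner(gate=None, margin=None)
    order = np.argsort(active)[::-1]
    top, second = active[order[0]], active[order[1]]
    margin = float(top / second) if second > zero_tol else float("inf")
    return GateWinner(gate=int(order[0]) + 1, margin=margin)
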