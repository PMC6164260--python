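"""Four-channel concentration thresholding of the amplifier output.

The output strand x (the amplifier's OB) displaces reporter strands A–D
from pre-formed carrier complexes A·L … D·L, releasing x/4 of each when
the channels are symmetric.  Dedicated threshold strands thr_1–thr_4 then
capture the released reporters irreversibly and much faster than they are
released.  A reporter is therefore observable free in solution only if the
input exceeds four times its threshold-strand concentration, which turns
the analogue input concentration into a band code on (A, B, C, D).

Per channel m the kinetics reduce to two ODEs; the free input x and the
carrier complexes are reconstructed from the exact conservation relations,
so those conservation laws hold structurally at every step:

    d[A_m]/dt = k_m [x] ([A_m·L_m]) - k_tm [A_m][thr_m]
    d[thr_m]/dt = -k_tm [A_m][thr_m]
    [A_m·L_m] = A_tot - [A_m] - thr_tot + [thr_m]
    [x] = x_tot - sum_m (thr_tot_m - [thr_m]) - sum_m [A_m]   (carriers = reporters)

Both reactions are irreversible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._integrate import euler, recorded_times

CHANNELS = ("A", "B", "C", "D")

#: Endpoint convention (seconds) reproducing the published four-scenario
#: operating table; see docs/methods.md for how this was established.
DEFAULT_DURATION = 6000.0
DEFAULT_DT = 0.05

__all__ = [
    "CHANNELS",
    "ThresholderParams",
    "ThresholderResult",
    "simulate_thresholder",
    "completion_limit",
]


def _as4(value, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (4,)).copy()
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


@dataclass(frozen=True)
class ThresholderParams:
    """Kinetic and stoichiometric parameters (SI units).

    k_release (k_m): rate at which the input displaces each reporter from
    its carrier, per-molar-per-second.  k_capture (k_tm): rate at which the
    threshold strand consumes the free reporter.  The mechanism requires
    k_capture >> k_release; a warning is issued if the ratio drops below
    100.  Carriers are fully pre-formed, so the carrier total equals the
    reporter total per channel.
    """

    k_release: np.ndarray = field(default=1e4)
    k_capture: np.ndarray = field(default=1e7)
    carrier_tot: np.ndarray = field(default=20e-9)
    thr_tot: np.ndarray = field(
        default_factory=lambda: np.array([0.25, 0.5, 0.75, 1.0]) * 1e-9
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_release", _as4(self.k_release, "k_release"))
        object.__setattr__(self, "k_capture", _as4(self.k_capture, "k_capture"))
        object.__setattr__(self, "carrier_tot", _as4(self.carrier_tot, "carrier_tot"))
        object.__setattr__(self, "thr_tot", _as4(self.thr_tot, "thr_tot"))
        with np.errstate(divide="ignore"):
            ratio = np.min(self.k_capture / np.where(self.k_release > 0,
                                                     self.k_release, np.inf))
        if ratio < 100:
            warnings.warn(
                f"k_capture/k_release = {ratio:.1f} < 100; thresholding "
                "requires capture to be much faster than release",
                stacklevel=2,
            )

    @property
    def capacity(self) -> float:
        """Total carrier capacity, the largest admissible input (molar)."""
        return float(self.carrier_tot.sum())


@dataclass(frozen=True)
class ThresholderResult:
    """Trajectory of the free reporters, threshold strands and free input."""

    time: np.ndarray
    free: np.ndarray       # (n, 4) free reporters A-D
    thr: np.ndarray        # (n, 4) free threshold strands
    x: np.ndarray          # (n,) free input reconstructed from conservation

    @property
    def free_endpoint(self) -> np.ndarray:
        return self.free[-1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.free, columns=list(CHANNELS))
        for m in range(4):
            frame[f"thr{m + 1}"] = self.thr[:, m]
        frame["x"] = self.x
        frame.insert(0, "time_s", self.time)
        return frame

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _free_x(y: np.ndarray, ob_final: float, params: ThresholderParams):
    thr = y[..., 4:8]
    free = y[..., 0:4]
    x = ob_final - (params.thr_tot.sum() - thr.sum(axis=-1)) - free.sum(axis=-1)
    return np.maximum(x, 0.0)


def simulate_thresholder(
    ob_final: float,
    params: ThresholderParams | None = None,
    dt: float = DEFAULT_DT,
    duration: float = DEFAULT_DURATION,
    record_every: int = 100,
) -> ThresholderResult:
    """Integrate the thresholding network for a given input concentration.

    ``ob_final`` is the amplifier output handed over at the stage boundary
    (molar).  The grid is ``duration / dt`` fixed Euler steps; the default
    endpoint of 6000 s is the convention that reproduces the published
    operating table.  An input exceeding the total carrier capacity is
    rejected.
    """
    params = params or ThresholderParams()
    if ob_final < 0:
        raise ValueError("ob_final must be non-negative")
    if ob_final > params.capacity:
        raise ValueError(
            f"ob_final {ob_final:.3e} M exceeds the carrier capacity "
            f"{params.capacity:.3e} M"
        )
    n_steps = int(round(duration / dt))

    def rhs(i: int, y: np.ndarray) -> np.ndarray:
        free, thr = y[..., 0:4], y[..., 4:8]
        x = _free_x(y, ob_final, params)[..., None]
        carriers = params.carrier_tot - free - params.thr_tot + thr
        release = params.k_release * x * carriers
        capture = params.k_capture * free * thr
        return np.concatenate([release - capture, -capture], axis=-1)

    y0 = np.concatenate([np.zeros(4), params.thr_tot])
    _, traj = euler(rhs, y0, dt, n_steps, record_every=record_every)
    times = recorded_times(dt, n_steps, record_every)
    return ThresholderResult(
        time=times,
        free=traj[:, 0:4],
        thr=traj[:, 4:8],
        x=_free_x(traj, ob_final, params),
    )


def completion_limit(ob_final: float, params: ThresholderParams | None = None) -> np.ndarray:
    """Analytic endpoint if release and capture both run to completion.

    With symmetric channels the input splits evenly, releasing
    ``ob_final/4`` of each reporter, of which the threshold strand removes
    its own total: the limit is ``max(0, ob_final/4 - thr_tot_m)`` per
    channel.  Valid only for equal release rates and equal carrier totals;
    serves as the independent oracle for the kinetic endpoint.
    """
    params = params or ThresholderParams()
    if ob_final < 0:
        raise ValueError("ob_final must be non-negative")
    if not (np.allclose(params.k_release, params.k_release[0])
            and np.allclose(params.carrier_tot, params.carrier_tot[0])):
        raise ValueError("completion_limit requires symmetric channels")
    return np.maximum(0.0, ob_final / 4.0 - params.thr_tot)
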