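"""Electrochemical pH control of a pH-sensitive (triplex) DNA nanoswitch.

A pair of voltage pulses drives water electrolysis at an electrode: the
opening pulse injects hydroxide into the reaction volume, raising the pH;
after a delay, an equal-and-opposite pulse restores it.  The nanoswitch is a
clamp-like DNA construct whose catalytic loop is sequestered below its
effective pKa and exposed above it, so the open fraction follows a
Henderson–Hasselbalch titration curve in the instantaneous pH.

The separation between the two pulse starts, ``t_open``, is the
information-carrying quantity: it sets how long the switch population stays
catalytically active.

Units are SI throughout (amperes, litres, seconds, molar).  Diffusion of the
electrogenerated ions is neglected: production is treated as instantaneous
and uniform over the volume, and the solution is modelled as an unbuffered
strong acid/base so the pH follows from the charge balance with the water
ion product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import physical_constants

#: Faraday constant, C/mol (Avogadro number times the elementary charge).
FARADAY = physical_constants["Faraday constant"][0]

__all__ = [
    "FARADAY",
    "ElectrochemicalParams",
    "PulseSchedule",
    "SwitchModel",
    "ActivityTrajectory",
    "compute_ion_production",
    "ph_from_net_ion_excess",
    "open_fraction",
    "build_activity_trajectory",
]


@dataclass(frozen=True)
class ElectrochemicalParams:
    """Electrolysis cell parameters.

    Parameters
    ----------
    current : float
        Electrolysis current in amperes.  The default 0.4 mA corresponds to
        a 4 V pulse across a 10 kOhm cell; voltage and resistance are kept
        only as metadata (``meta``), the model is parameterized by current.
    volume : float
        Reaction volume in litres.
    pulse_duration : float
        Length of each voltage pulse in seconds.
    initial_pH : float
        Resting pH of the solution before any pulse.
    water_ion_product : float
        Kw in molar^2, used in the charge balance.
    """

    current: float = 0.4e-3
    volume: float = 100e-6
    pulse_duration: float = 20.0
    initial_pH: float = 5.5
    water_ion_product: float = 1e-14
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.current <= 0:
            raise ValueError("current must be positive")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if not 0 < self.initial_pH < 14:
            raise ValueError("initial_pH must lie in (0, 14)")
        if self.water_ion_product <= 0:
            raise ValueError("water_ion_product must be positive")


@dataclass(frozen=True)
class PulseSchedule:
    """Timing of the opening/closing voltage pulse pair.

    ``separation`` is the delay between the starts of the opening and the
    closing pulse — the quantity referred to as ``t_open`` downstream.  The
    opening pulse raises the pH; the closing pulse has equal and opposite
    amplitude and restores it.
    """

    open_pulse_start: float = 0.0
    separation: float = 3000.0

    def __post_init__(self) -> None:
        if self.open_pulse_start < 0:
            raise ValueError("open_pulse_start must be non-negative")
        if self.separation <= 0:
            raise ValueError("separation must be positive")

    @property
    def t_open(self) -> float:
        return self.separation


@dataclass(frozen=True)
class SwitchModel:
    """pH response of the nanoswitch population.

    ``pKa`` is the effective pKa of the triplex-to-duplex transition;
    ``total_switch`` the total switch concentration in molar (conserved).
    """

    pKa: float = 7.5
    total_switch: float = 0.0

    def __post_init__(self) -> None:
        if self.total_switch < 0:
            raise ValueError("total_switch must be non-negative")


@dataclass(frozen=True)
class ActivityTrajectory:
    """Precomputed time course of pH and switch open fraction.

    ``activity`` is the open fraction [Open]/[Total], in [0, 1] pointwise,
    evaluated on a uniform ``time`` grid (seconds).
    """

    time: np.ndarray
    activity: np.ndarray
    pH: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        activity = np.asarray(self.activity, dtype=float)
        pH = np.asarray(self.pH, dtype=float)
        if not (len(time) == len(activity) == len(pH)):
            raise ValueError("time, activity and pH must have equal length")
        if np.any(activity < 0) or np.any(activity > 1):
            raise ValueError("activity must lie in [0, 1] pointwise")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "activity", activity)
        object.__setattr__(self, "pH", pH)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "pH": self.pH, "activity": self.activity}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_ion_production(params: ElectrochemicalParams, duration: float) -> float:
    """Concentration of ions produced by electrolysis over ``duration`` seconds.

    n = I*dt/(N_A*e) moles, delivered into ``params.volume`` litres, i.e.
    I*duration/(F*v) molar.  Linear in both current and duration.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    return params.current * duration / (FARADAY * params.volume)


def ph_from_net_ion_excess(net_oh_excess, params: ElectrochemicalParams):
    """pH after adding a signed net hydroxide excess to the resting solution.

    The solution is treated as an unbuffered strong acid/base: the initial
    state contributes a fixed net strong-acid excess consistent with
    ``initial_pH``, and the electrolysis adds ``net_oh_excess`` molar of
    hydroxide (negative values mean added protons).  The proton
    concentration solves the charge balance h^2 + b*h - Kw = 0, where b is
    the total net base excess; the numerically stable quadratic root is used
    on each branch so the function is continuous and never returns NaN.

    Accepts scalars or arrays.
    """
    kw = params.water_ion_product
    h0 = 10.0 ** (-params.initial_pH)
    base0 = -(h0 - kw / h0)  # signed net strong-base excess of the resting state
    b = np.asarray(net_oh_excess, dtype=float) + base0
    disc = np.sqrt(b * b + 4.0 * kw)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(b > 0, 2.0 * kw / (b + disc), 0.5 * (disc - b))
    ph = -np.log10(h)
    return float(ph) if np.isscalar(net_oh_excess) else ph


def open_fraction(pH, pKa: float = 7.5):
    """Open fraction of the switch, 1/(1 + 10^(pKa - pH)).

    Strictly increasing in pH, equal to 1/2 at pH == pKa, saturating at 0
    and 1.  Accepts scalars or arrays.
    """
    frac = 1.0 / (1.0 + 10.0 ** (np.asarray(pKa, dtype=float) - np.asarray(pH, dtype=float)))
    return float(frac) if np.isscalar(pH) and np.isscalar(pKa) else frac


def net_hydroxide_timecourse(schedule: PulseSchedule, params: ElectrochemicalParams, time):
    """Signed net hydroxide excess (molar) at each time point.

    The opening pulse accumulates hydroxide linearly over its duration; the
    closing pulse removes it at the same rate (equal and opposite), so the
    excess returns exactly to zero afterwards.
    """
    time = np.asarray(time, dtype=float)
    rate = params.current / (FARADAY * params.volume)  # molar per second
    dur = params.pulse_duration
    t0 = schedule.open_pulse_start
    up = np.clip(time - t0, 0.0, dur)
    down = np.clip(time - t0 - schedule.separation, 0.0, dur)
    return rate * (up - down)


def build_activity_trajectory(
    schedule: PulseSchedule | None,
    params: ElectrochemicalParams,
    switch: SwitchModel,
    time_grid=None,
    dt: float = 0.05,
    n_steps: int = 150_000,
) -> ActivityTrajectory:
    """Precompute the pH and switch-activity time course for a pulse pair.

    The trajectory is evaluated on ``time_grid`` if given, otherwise on a
    uniform grid of ``n_steps`` points spaced ``dt`` seconds apart.  The pH
    rises (linearly in net ion excess) during the opening pulse, stays
    constant between pulses, and is restored by the closing pulse; the
    activity is the open fraction at the switch pKa.  The chemistry is not
    coupled back to the pH, so the whole trajectory can be computed in
    advance.  ``schedule=None`` means no pulses: the pH stays at its
    resting value and the activity at the titration floor.
    """
    if time_grid is None:
        time_grid = np.arange(n_steps) * dt
    else:
        time_grid = np.asarray(time_grid, dtype=float)
    if schedule is None:
        ph = np.full_like(time_grid, params.initial_pH)
        return ActivityTrajectory(
            time=time_grid, activity=open_fraction(ph, switch.pKa), pH=ph
        )
    if schedule.separation < params.pulse_duration:
        raise ValueError("pulse separation must be at least one pulse duration")
    end = schedule.open_pulse_start + schedule.separation + params.pulse_duration
    if end > time_grid[-1]:
        raise ValueError(
            f"schedule extends to t={end:.1f} s, beyond the grid end "
            f"{time_grid[-1]:.1f} s"
        )
    net = net_hydroxide_timecourse(schedule, params, time_grid)
    ph = ph_from_net_ion_excess(net, params)
    act = open_fraction(ph, switch.pKa)
    return ActivityTrajectory(time=time_grid, activity=act, pH=ph)
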