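"""Gated amplification cycle: stoichiometry, conservation and response shape.

Most tests run on a coarsened grid (0.5 s steps over the same 125 min
window); the step-size convergence test ties that back to the 0.05 s
convention.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

import dnacomputer as dc
from dnacomputer import catalytic
from dnacomputer.electrochemistry import (
    ActivityTrajectory,
    ElectrochemicalParams,
    PulseSchedule,
    SwitchModel,
    build_activity_trajectory,
)

DT, NSTEPS = 0.5, 15_000  # coarse grid: 125 min window


@pytest.fixture()
def rates():
    return catalytic.CycleRates()


@pytest.fixture()
def operating_point():
    return catalytic.CycleInitialState(substrate=11e-9, fuel=11e-9,
                                       total_switch=1.7e-9)


def flat_activity(value, dt=DT, n_steps=NSTEPS):
    t = np.arange(n_steps) * dt
    return ActivityTrajectory(time=t, activity=np.full(n_steps, value),
                              pH=np.full(n_steps, 7.5))


def pulsed_activity(t_open, dt=DT, n_steps=NSTEPS):
    grid = np.arange(n_steps) * dt
    return build_activity_trajectory(
        PulseSchedule(0.0, t_open), ElectrochemicalParams(),
        SwitchModel(total_switch=1.7e-9), time_grid=grid,
    )


def test_inactive_catalyst_produces_almost_nothing(operating_point, rates):
    res = catalytic.simulate_cycle(operating_point, rates, flat_activity(0.0))
    assert res.ob_final < 0.01 * operating_point.substrate


def test_one_output_per_signal_with_excess_fuel(rates):
    """Each turnover releases one signal then one output strand; with fuel
    in excess the two final concentrations coincide."""
    init = catalytic.CycleInitialState(substrate=10e-9, fuel=30e-9,
                                       total_switch=2e-9)
    res = catalytic.simulate_cycle(init, rates, flat_activity(1.0, 0.5, 60_000))
    ob, sb = res.ob_final, res.diagnostics["final_signal"]
    assert ob > 0.5 * init.substrate  # substantial conversion
    assert ob == pytest.approx(sb, rel=0.05)
    # the gap is exactly the post-release intermediate still awaiting fuel
    i2 = res.species[-1, 3]
    assert (sb - ob) == pytest.approx(i2, abs=1e-15)


def test_switch_conservation(operating_point, rates):
    res = catalytic.simulate_cycle(operating_point, rates, pulsed_activity(900.0))
    assert res.diagnostics["switch_conservation_drift"] < 1e-12 * 1.7e-9


def test_conserved_moieties_from_stoichiometry(operating_point, rates):
    """Every left-null-space vector of the stoichiometry matrix defines a
    conserved linear combination along the trajectory."""
    res = catalytic.simulate_cycle(operating_point, rates, pulsed_activity(900.0))
    conserved = null_space(catalytic.STOICHIOMETRY.T)
    combos = res.species @ conserved  # (n_recorded, n_laws)
    drift = np.max(np.abs(combos - combos[0]), axis=0)
    assert np.all(drift < 1e-12 * np.max(np.abs(combos[0])))


def test_products_nondecreasing_without_reverse_rates(operating_point):
    irrev = catalytic.CycleRates(unbind=0.0, rebind=0.0)
    res = catalytic.simulate_cycle(operating_point, irrev, pulsed_activity(900.0))
    assert np.all(np.diff(res.species[:, 6]) >= -1e-18)  # OB
    assert np.all(np.diff(res.species[:, 4]) >= -1e-18)  # SB


def test_gated_at_full_activity_matches_ungated_oracle(operating_point, rates):
    """With the switch pinned open the gate multiplier must be inert: an
    independent ungated integration of the same network is the oracle."""
    res = catalytic.simulate_cycle(operating_point, rates, flat_activity(1.0))

    def ungated(t, y):
        s, c, i1, i2, sb, f, ob, w = y
        r1 = rates.bind * c * s - rates.unbind * i1
        r2 = rates.release * i1 - rates.rebind * i2 * sb
        r3 = rates.fuel * i2 * f
        return [-r1, -r1 + r3, r1 - r2, r2 - r3, r2, -r3, r3, r3]

    sol = solve_ivp(ungated, (0, DT * (NSTEPS - 1)), operating_point.as_vector(),
                    rtol=1e-10, atol=1e-16)
    assert res.ob_final == pytest.approx(sol.y[6, -1], rel=5e-3)


def test_euler_agrees_with_adaptive_integrator():
    """Fixed-step 0.05 s Euler vs LSODA at the reference illustration
    settings (substrate 10 nM, fuel 13 nM, switch 5 nM, separation 3000 s)."""
    init = catalytic.CycleInitialState(substrate=10e-9, fuel=13e-9,
                                       total_switch=5e-9)
    rates = catalytic.CycleRates()
    activity = pulsed_activity(3000.0, dt=0.05, n_steps=150_000)
    euler_res = catalytic.simulate_cycle(init, rates, activity)
    lsoda_res = catalytic.simulate_cycle(init, rates, activity, method="lsoda")
    assert euler_res.ob_final == pytest.approx(lsoda_res.ob_final, rel=5e-3)


def test_closing_pulse_restores_switch_pool(rates):
    """After the closing pulse the free switch pool repartitions to closed
    and output production stalls."""
    init = catalytic.CycleInitialState(substrate=10e-9, fuel=13e-9,
                                       total_switch=5e-9)
    res = catalytic.simulate_cycle(init, rates, pulsed_activity(3000.0))
    # free switch (column 1) returns towards its initial total as
    # intermediates drain after closing
    late = res.species[res.time > 6000.0]
    assert late[-1, 1] == pytest.approx(5e-9, rel=0.05)
    # production rate after closing is far below the open-window rate
    ob = res.species[:, 6]
    t = res.time
    open_rate = (ob[t.searchsorted(2500.0)] - ob[t.searchsorted(1500.0)]) / 1000.0
    late_rate = (ob[-1] - ob[t.searchsorted(6500.0)]) / (t[-1] - 6500.0)
    assert late_rate < 0.1 * open_rate


def test_response_monotone_with_decreasing_marginal_gain(operating_point, rates):
    topen = [60, 240, 600, 1200, 2400, 4200]
    table = catalytic.ob_final_vs_topen(
        operating_point, rates, ElectrochemicalParams(), SwitchModel(),
        topen, dt=DT, n_steps=NSTEPS,
    )
    ob = table.ob_final_M.to_numpy()
    assert np.all(np.diff(ob) > 0)
    gain = np.diff(ob) / np.diff(topen)
    assert np.all(np.diff(gain) < 0)


def test_interior_switch_concentration_maximizes_dynamic_range(rates):
    """The 100 s -> 900 s output difference peaks at an intermediate switch
    concentration: too little gives no turnover, too much finishes early."""
    diffs = []
    for switch_nM in [0.5, 5.0, 40.0]:
        init = catalytic.CycleInitialState(substrate=10e-9, fuel=13e-9,
                                           total_switch=switch_nM * 1e-9)
        diffs.append(catalytic.ob_100_900(
            init, rates, ElectrochemicalParams(), SwitchModel(),
            dt=DT, n_steps=NSTEPS,
        ))
    assert diffs[1] > diffs[0] and diffs[1] > diffs[2]


def test_higher_substrate_and_fuel_raise_output(rates):
    lo = catalytic.CycleInitialState(substrate=10e-9, fuel=13e-9,
                                     total_switch=5e-9)
    hi = catalytic.CycleInitialState(substrate=30e-9, fuel=39e-9,
                                     total_switch=5e-9)
    act = pulsed_activity(900.0)
    ob_lo = catalytic.simulate_cycle(lo, rates, act).ob_final
    ob_hi = catalytic.simulate_cycle(hi, rates, act).ob_final
    assert ob_hi > ob_lo


def test_topen_beyond_window_rejected(operating_point, rates):
    with pytest.raises(ValueError, match="window"):
        catalytic.ob_final_vs_topen(
            operating_point, rates, ElectrochemicalParams(), SwitchModel(),
            [DT * NSTEPS + 100.0], dt=DT, n_steps=NSTEPS,
        )


def test_operating_range_calibration(operating_point, rates):
    """At the stated operating point the output spans roughly 1.5-5 nM for
    t_open between about one minute and forty minutes."""
    table = catalytic.ob_final_vs_topen(
        operating_point, rates, ElectrochemicalParams(), SwitchModel(),
        [60.0, 2400.0], dt=DT, n_steps=NSTEPS,
    )
    ob_nM = table.ob_final_M.to_numpy() * 1e9
    assert ob_nM[0] == pytest.approx(1.5, abs=0.5)
    assert ob_nM[1] == pytest.approx(5.0, abs=1.0)
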