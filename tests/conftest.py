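"""Shared fixtures: published operating-table values and heavy pipeline runs."""

import numpy as np
import pytest

import dnacomputer as dc

# Four-cycle operating scenario: nominal amplifier output (nM), thresholder
# endpoint A-D (nM), endpoint active gates G1-G4 (pM), initial and final
# ensemble state vectors.
OPERATING_TABLE = [
    {
        "ob_nM": 1.5,
        "thresh_nM": [0.122, 0.004, 0.001, 0.0],
        "gates_pM": [96.084, 2.841, 0.931, 0.0],
        "s_initial": [1.0, 0.0, 0.0],
        "s_final": [0.0296, 0.0097, 0.9995],
        "winner": 1,
    },
    {
        "ob_nM": 2.8,
        "thresh_nM": [0.443, 0.194, 0.015, 0.002],
        "gates_pM": [8.520, 86.072, 6.229, 0.571],
        "s_initial": [0.0296, 0.0097, 0.9995],
        "s_final": [0.9951, 0.0027, 0.0985],
        "winner": 2,
    },
    {
        "ob_nM": 3.9,
        "thresh_nM": [0.715, 0.465, 0.215, 0.024],
        "gates_pM": [0.0, 1.044, 69.702, 3.560],
        "s_initial": [0.9951, 0.0027, 0.0985],
        "s_final": [0.0673, 0.9977, 0.0],
        "winner": 3,
    },
    {
        "ob_nM": 5.0,
        "thresh_nM": [0.987, 0.737, 0.487, 0.237],
        "gates_pM": [0.0, 0.0, 1.377, 39.846],
        "s_initial": [0.0673, 0.9977, 0.0],
        "s_final": [0.9994, 0.0345, 0.0],
        "winner": 4,
    },
]


@pytest.fixture(scope="session")
def table3_scenario():
    """Full-precision four-cycle pipeline run at the published conventions."""
    return dc.run_table3_scenario(dc.CycleConfig())


@pytest.fixture(scope="session")
def gates_from_printed():
    """Gate-stage results seeded with the published thresholder endpoints."""
    results = []
    for row in OPERATING_TABLE:
        inputs = np.asarray(row["thresh_nM"]) * 1e-9
        results.append(dc.simulate_gates(inputs))
    return results


@pytest.fixture()
def coarse_config():
    """Cheap configuration (0.5 s steps, same physical durations)."""
    return dc.CycleConfig().coarse(10)
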