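"""Fixed-step explicit Euler integration shared by the stage simulators.

The published convention for every stage is a uniform grid of 0.05 s steps,
which is comfortably stable here: the fastest pseudo-first-order rates in
the networks are of order 1e-2 per second, four orders of magnitude below
the step limit.  The right-hand sides broadcast over leading axes, so a
batch of parameter sets can be integrated in one pass.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

# Concentrations more negative than this (molar) indicate a genuinely
# unstable step rather than floating-point noise.
_NEG_TOL = 1e-15


def euler(
    rhs: Callable[[int, np.ndarray], np.ndarray],
    y0: np.ndarray,
    dt: float,
    n_steps: int,
    record_every: int = 0,
    clip_negative: bool = True,
):
    """Integrate ``dy/dt = rhs(step_index, y)`` with fixed-step Euler.

    ``rhs`` receives the current step index (so precomputed drivers such as
    the switch-activity trajectory can be indexed directly) and the state
    array; the state may carry leading batch axes.

    Returns ``(y_final, trajectory)`` where ``trajectory`` stacks the state
    every ``record_every`` steps (including step 0 and the final step), or
    is ``None`` when ``record_every`` is 0.

    A step that drives any component below a small negative tolerance
    raises, pointing at the step size; roundoff-level negatives are clipped
    to zero when ``clip_negative`` is set.
    """
    y = np.array(y0, dtype=float)
    recorded = []
    if record_every:
        recorded.append(y.copy())
    for i in range(n_steps):
        y = y + dt * rhs(i, y)
        if np.any(y < -_NEG_TOL):
            raise RuntimeError(
                f"negative concentration at step {i + 1} (t={(i + 1) * dt:.3f} s); "
                "reduce the step size"
            )
        if clip_negative:
            np.maximum(y, 0.0, out=y)
        if record_every and ((i + 1) % record_every == 0 or i == n_steps - 1):
            recorded.append(y.copy())
    traj = np.stack(recorded) if record_every else None
    return y, traj


def recorded_times(dt: float, n_steps: int, record_every: int) -> np.ndarray:
    """Time stamps matching the trajectory layout produced by :func:`euler`."""
    idx = [0] + [i for i in range(record_every, n_steps + 1, record_every)]
    if idx[-1] != n_steps:
        idx.append(n_steps)
    return np.asarray(idx, dtype=float) * dt
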