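"""Tensor finite state machine driven by the active logic gate.

An ensemble of three-state machines (F: move forward, L: rotate left,
R: rotate right) is immobilized on a surface.  The ensemble state is a
unit-norm non-negative 3-vector s over (F, L, R); the input is a unit-norm
4-vector g over the sensor signals (f, f-bar, l-bar, l), obtained by
normalizing the endpoint active-gate concentrations.  Injected transition
rules encode a 3x4x3 tensor T of unit basis vectors (zero for the four
sensor/state combinations that cannot occur), and the settled final state
is the normalized contraction

    psi_r = s_p g_q T_pqr .

The raw contraction is not unit-norm in general, so the result is
renormalized; the physical reading is that every machine ends in *some*
state.  The approach to the final state is modelled as single-exponential
with one effective rate for transition-rule binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

STATE_LABELS = ("F", "L", "R")
INPUT_LABELS = ("f", "f_bar", "l_bar", "l")

#: Left-wall-follower transition rules as (state, input, next-state) labels.
LEFT_WALL_RULES = (
    ("F", "f", "R"),
    ("F", "f_bar", "F"),
    ("F", "l_bar", "L"),
    ("F", "l", "F"),
    ("L", "l_bar", "L"),
    ("L", "l", "F"),
    ("R", "f", "R"),
    ("R", "f_bar", "F"),
)

__all__ = [
    "STATE_LABELS",
    "INPUT_LABELS",
    "LEFT_WALL_RULES",
    "FsmDynamicsParams",
    "normalize",
    "tensor_from_rules",
    "load_transition_rules",
    "build_left_wall_tensor",
    "fsm_transition",
    "fsm_dynamics",
]


@dataclass(frozen=True)
class FsmDynamicsParams:
    """Settling kinetics of the ensemble.

    ``rate``: effective first-order rate for the state change (per second);
    the default 1e-3 /s reflects hybridization to a sparse surface-bound
    target at low solution concentration.  ``block_interval``: sampling
    interval for the block-raster visualisation (seconds).  ``settle_time``:
    time allowed for the transition within one operating cycle.
    """

    rate: float = 1e-3
    block_interval: float = 240.0
    settle_time: float = 36_000.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.block_interval <= 0 or self.settle_time <= 0:
            raise ValueError("times must be positive")


def normalize(v) -> np.ndarray:
    """Scale a non-negative, non-zero vector to unit Euclidean norm."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("state/input vectors must be non-negative")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot normalize the zero vector")
    return v / norm


def tensor_from_rules(rules) -> np.ndarray:
    """Build the 3x4x3 transition tensor from (state, input, next) triples.

    Unlisted (state, input) pairs are left as zero vectors, marking
    transitions that cannot occur.
    """
    tensor = np.zeros((3, 4, 3))
    for state, signal, nxt in rules:
        try:
            p = STATE_LABELS.index(state)
            q = INPUT_LABELS.index(signal)
            r = STATE_LABELS.index(nxt)
        except ValueError as err:
            raise ValueError(f"unknown label in rule {(state, signal, nxt)}") from err
        if tensor[p, q].any():
            raise ValueError(f"duplicate rule for state {state!r}, input {signal!r}")
        tensor[p, q, r] = 1.0
    return tensor


def load_transition_rules(path=None) -> np.ndarray:
    """Read a transition tensor from a plain-text rule table.

    Each non-comment line holds ``state input next_state`` separated by
    whitespace.  With no ``path`` the packaged left-wall-follower table is
    loaded.
    """
    if path is None:
        text = (
            resources.files("dnacomputer") / "data" / "left_wall_rules.tsv"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"malformed rule line: {line!r}")
        rules.append(tuple(parts))
    return tensor_from_rules(rules)


def build_left_wall_tensor() -> np.ndarray:
    """Transition tensor of the left-wall-following maze robot.

    Eight rules are defined; the four undefined combinations (state L with
    a forward-sensor signal, state R with a left-sensor signal) are zero
    vectors.
    """
    return tensor_from_rules(LEFT_WALL_RULES)


def fsm_transition(s, g_raw, tensor: np.ndarray) -> np.ndarray:
    """Settled final state from the current state and raw gate vector.

    ``g_raw`` is the un-normalized endpoint active-gate concentration
    vector; it is normalized before the contraction, and the contraction
    result is renormalized.  A zero input, or an input whose mass falls
    entirely on undefined rules, raises.
    """
    s = np.asarray(s, dtype=float)
    g = normalize(g_raw)
    psi = np.einsum("p,q,pqr->r", s, g, tensor)
    norm = np.linalg.norm(psi)
    if norm < 1e-300:
        raise ValueError("all input mass falls on undefined transitions")
    return psi / norm


def fsm_dynamics(s_prev, s_final, params: FsmDynamicsParams, t):
    """State vector during the single-exponential approach to ``s_final``.

    s(t) = normalize(s_final + (s_prev - s_final) exp(-rate t)); equals
    ``s_prev`` at t = 0 and converges to ``s_final``.  ``t`` may be a
    scalar or an array (seconds); an array returns one row per time.
    """
    s_prev = np.asarray(s_prev, dtype=float)
    s_final = np.asarray(s_final, dtype=float)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    decay = np.exp(-params.rate * t_arr)[:, None]
    raw = s_final[None, :] + (s_prev - s_final)[None, :] * decay
    out = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out
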