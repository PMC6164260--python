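# Methods

This note documents the models implemented in `dnacomputer`, the defaults
and where they come from, the numerical conventions, and what the tests do
and do not establish.

## Electrochemistry and switch gating

Electrolysis is reduced to stoichiometry: a pulse of current *I* (default
0.4 mA, i.e. 4 V across a 10 kΩ cell — the cell voltage and resistance are
kept only as metadata) for Δt seconds injects *I*Δt/(F·v) molar of
hydroxide uniformly into the volume v (default 100 µL). Ion diffusion is
neglected; production is instantaneous and uniform. The closing pulse is
equal and opposite, so the net ion excess returns exactly to zero and the
pH to its resting value (5.5) — bit-exact up to the quadratic solve, tested
to 1e-9 pH units.

The solution is modelled as an **unbuffered strong acid/base**: the pH
solves the charge balance h² + b·h − K_w = 0, where b is the signed net
strong-base excess (electrolysis plus the resting offset). This is the
simplest chemistry consistent with a stated resting pH and pure
electrolysis stoichiometry; buffering by DNA, salts or dissolved CO₂ is
ignored (see Limitations). The numerically stable quadratic root is used on
each sign branch, so the function is continuous, monotone and NaN-free for
any input.

Switch opening is equilibrium titration: open fraction = 1/(1 + 10^(pKa −
pH)), pKa = 7.5. At the resting pH the activity floor is 1/101 ≈ 0.0099 —
the switch is never perfectly off, which produces a small leak of catalysis
throughout the reaction window. During the 20 s pulse the pH moves
progressively (linear ion accumulation) rather than as a step; over open
windows of minutes to hours the difference is negligible, but it is the
convention used throughout.

The activity trajectory is precomputed on the simulation grid and is not
coupled back to the chemistry (the DNA concentrations are nanomolar; their
proton exchange is irrelevant at these ion quantities).

## Amplification cycle

The amplifier follows the entropy-driven catalysis scheme: catalyst C binds
the substrate toehold (S + C ⇌ I1), branch migration releases the signal
strand (I1 ⇌ I2 + SB), and fuel displaces the catalyst (I2 + F → C + OB +
W). The pH gate multiplies the *free* catalyst concentration entering the
binding step by the activity; species with the switch bound (I1, I2) react
at full rate, implementing the rule that a nanoswitch cannot reclose while
its loop is engaged. After the closing pulse the free pool repartitions to
closed and production stalls at the leak floor.

Rate constants are configuration, not physics baked into the code
(`data/default_config.yaml`). The shipped defaults — bind 1e6 /M/s, unbind
0.02 /s, release 0.05 /s, rebind 1e6 /M/s, fuel 2e5 /M/s — are within the
published range for toehold-mediated strand displacement and were
calibrated once, coarsely, so that the documented operating point (switch
1.7 nM, substrate = fuel = 11 nM, 125 min window) maps t_open ≈ 1 min →
[OB]_final ≈ 1.5 nM and t_open ≈ 40 min → ≈ 5 nM. No quantitative claim
rests on these values: the amplifier is validated by structural properties
(conservation laws from the stoichiometry left-null space, one output per
signal strand, saturating monotone response, an interior switch
concentration maximizing the 100 s→900 s dynamic range [OB]₁₀₀₋₉₀₀).
Signal-strand rebinding is what bends the response at high conversion; with
it disabled the output is provably monotone in time.

## Thresholder

Per channel m: d[A_m]/dt = k_m[x]([A_m·L_m]) − k_tm[A_m][thr_m],
d[thr_m]/dt = −k_tm[A_m][thr_m], with the carrier complex and free input x
reconstructed from the exact conservation relations (so those hold
structurally at every step; the integrator cannot drift them). Both
reactions are irreversible. Defaults: k_m = 1e4 /M/s, k_tm = 1e7 /M/s
(capture must dominate release; a warning fires below a 100× ratio),
carriers 20 nM per channel, thresholds 0.25/0.5/0.75/1 nM. The analytic
completion endpoint max(0, x/4 − thr_m) is the independent oracle: the
kinetic endpoint converges to it, and it places reporter visibility exactly
at four times the matching threshold concentration.

Per-channel release rates are kept as a 4-vector so asymmetric designs are
expressible; the even x/4 split is a consequence of symmetric defaults, not
an imposed rule.

## Logic gates

The seven irreversible bimolecular reactions (gate m activated by reporter
m, deactivated by reporter m+1; gate 4 never deactivated) are integrated
as eleven ODEs; reporters B, C, D each feed two sinks. Defaults: gates at
0.1 nM; activation/deactivation at 6e6 /M/s (gates 1–2), 2.5e6 /M/s
(gate 3) and 2.5e5 /M/s (gate 4 activation). The dumb-bell structural
mechanics (stem opening, lock/identity/FSM-binding domains) are
documentation; the kinetics are these seven reactions. Premature gate–FSM
binding is not modelled: stage ordering is enforced instead, since a
transition cannot occur before the rules are injected.

## Endpoint conventions

The grids use 0.05 s fixed-step explicit Euler throughout, matching the
published convention (the amplification window is 150 000 steps = 125 min).
This is far from the stability limit — the fastest pseudo-first-order rate
in any network is ~1e-2 /s — and agrees with an adaptive LSODA integration
to well under 0.5% (tested). An adaptive method is available behind
`method="lsoda"`.

The operating-table endpoint times are not all stated in the source
material. They were established by matching the printed four-scenario
table against the simulated trajectories: the thresholder block corresponds
to **t = 6000 s** and the gate block to **t = 15000 s** (every printed
value then agrees to its 3-decimal precision). These are the package
defaults; the gate result also carries a stationarity diagnostic
(max |d[G^act]/dt| at the endpoint) rather than using stationarity as a
stopping rule, because the slow gate-4 channel is still creeping at any
practical stopping threshold.

A related quirk: the published gate values are reproduced exactly when the
gate stage is seeded with the *rounded* (3 d.p.) thresholder endpoints,
indicating the original per-stage computations exchanged rounded values.
The orchestrator hands over full precision — physically the right thing —
which shifts gate endpoints by at most ~0.15 pM; the acceptance checks
cover both conventions within their tolerances.

## Finite state machine

States (F, L, R) and inputs (f, f̄, l̄, l) are unit-norm non-negative
vectors; the input is the normalized raw active-gate vector. The final
state is the contraction Ψ_r = s_p g_q T_pqr, renormalized. Renormalization
is required because the raw contraction is not unit-norm (for the
second operating cycle it is (1.0216, 0.0028, 0.1011), hand-checkable);
physically, every machine ends in some state. The raw gate vector is
normalized before zero rules remove mass — the convention consistent with
the published final states. The four undefined tensor entries are the
(state, input) pairs the encoder can never produce; the tensor row listed
under the R block for input 4 is read as T₃₄ (a fourth state index would be
dimensionally impossible for a three-state machine) and set to zero.

Settling is single-exponential at 1e-3 /s (hybridization to a sparse
surface target at low concentration); over a 10 h cycle exp(−36) leaves the
final state to machine precision, and the "probability of being in a
state" is taken to be the state-vector element itself (not its square) —
the >99% occupancy conclusion holds under either reading. The block-raster
output samples the settling curve every 4 min.

## Orchestrator, encoder and maze

`ideal_ob` mode injects the nominal output concentration at the
thresholder boundary (the exact-OB convention of the reference scenario);
`full_chemistry` derives it from a pulse schedule. Only input 1's pulse
delay (≈1 min) is fixed by design; delays for inputs 2–4 are obtained at
run time by bisecting the simulated t_open response
(`calibrate_topen`), since they depend on the configured amplifier rates.
Flushing is represented by construction: each stage starts from fresh
pools, and only the state vector crosses cycle boundaries.

The sensor encoder is a priority scheme: wall ahead → input 1; else a
dominantly-rotating-right machine reports the cleared path → input 2; else
a clear left → input 3; else → input 4. This is the unique priority
consistent with the defined transition rules and guarantees exactly one
true input. Geometry is a unit grid with 90° headings; rotating states
consume a full cycle without translation. One consequence is worth noting:
with adjacent-cell sensors and rotation-in-place, the left sensor
immediately after a left rotation always faces the robot's own previous
(free) cell, so an "outer corner" cannot produce the input-4-after-input-3
pattern; left-wall following is exact for corridors and right-turning
corners (and the scripted four-cycle scenario), while open areas produce
the encoder's defined but non-navigating behaviour.

## Problem sizes and determinism

Default runs use the published grids: amplification 1.5e5 steps, thresholder
1.2e5, gates 3e5 per cycle; the four-cycle scenario is ~2e6 Euler steps and
runs in ~30 s. Property sweeps in the test suite use a 10×-coarsened grid
(0.5 s steps, identical physical durations), which the convergence test
ties back to the reference grid. Every computation is deterministic —
there is no sampling anywhere — so repeated runs are bit-identical.

## Limitations

- No buffering, electrode geometry, double-layer effects or pH gradients;
  real electrolysis in a buffered biological medium would need far more
  charge for the same pH swing.
- Solution-phase rate constants are used even though the switch and FSM
  could be surface-immobilized; the amplifier rates are representative,
  not fitted to measurements of a built device.
- No sequence-level leak or crosstalk modelling: species interact only
  through the declared reactions. Passing tests therefore establish the
  *systems-level* logic of the design, not the feasibility of any
  particular DNA sequence set.
- The FSM transition is an algebraic idealization of transition-rule
  hybridization with a single effective rate; premature gate binding and
  readout (fluorophore/quencher) hardware are out of scope.
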