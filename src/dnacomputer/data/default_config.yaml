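# Default operating parameters for the bioelectronic DNA computer simulator.
# Units: mA, uL, s, nM as indicated by the key suffixes; rate constants in
# /M/s (bimolecular) or /s (unimolecular).

electrochemistry:
  current_mA: 0.4          # 4 V across a 10 kOhm cell
  voltage_V: 4.0           # metadata only; the model uses the current
  resistance_kOhm: 10.0
  volume_uL: 100.0
  pulse_duration_s: 20.0
  initial_pH: 5.5

switch:
  pKa: 7.5                 # effective pKa of the triplex-duplex transition
  total_nM: 1.7

catalytic_cycle:
  substrate_nM: 11.0
  fuel_nM: 11.0
  dt_s: 0.05
  n_steps: 150000          # 125 min reaction window
  # Entropy-driven amplifier rate constants.  The kinetic scheme follows the
  # published model of the entropy-driven catalytic cycle; the values below
  # are representative of the published toehold-mediated strand-displacement
  # fits for that system, calibrated so the operating point above yields a
  # final output of roughly 1.5-5 nM for t_open between ~1 and ~40 min.
  rates:
    bind: 1.0e6            # catalyst + substrate toehold binding, /M/s
    unbind: 0.02           # dissociation of the toehold complex, /s
    release: 0.05          # signal-strand release (branch migration), /s
    rebind: 1.0e6          # signal-strand rebinding (entropic brake), /M/s
    fuel: 2.0e5            # fuel displacement regenerating the catalyst, /M/s

thresholder:
  k_m: 1.0e4               # carrier displacement by the output, /M/s
  k_tm: 1.0e7              # threshold-strand capture, /M/s (must be >> k_m)
  A_tot_nM: 20.0           # carrier complexes per channel
  thr_tot_nM: [0.25, 0.5, 0.75, 1.0]
  duration_s: 6000.0       # endpoint convention, see docs/methods.md

gates:
  k_act: [6.0e6, 6.0e6, 2.5e6, 2.5e5]
  k_deact: [6.0e6, 6.0e6, 2.5e6]
  gate_tot_nM: 0.1
  duration_s: 15000.0      # endpoint convention, see docs/methods.md

fsm:
  rate_per_s: 1.0e-3       # effective transition-rule binding rate
  block_interval_s: 240.0  # block-raster sampling interval
  settle_time_s: 36000.0   # one 10 h operating cycle

orchestrator:
  mode: ideal_ob           # ideal_ob | full_chemistry
  encoding:
    ob_nM: {1: 1.5, 2: 2.8, 3: 3.9, 4: 5.0}
    t_open_s: {1: 60.0}    # inputs 2-4 are calibrated at run time
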