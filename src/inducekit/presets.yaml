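# Named parameter sets used throughout the package's analyses and examples.
# Concentration-valued fields accept unit suffixes (M, mM, uM, nM, pM);
# rates in motif blocks are dimensionless (units of gamma*Kd) unless the
# block is dimensional (hill_compare_*: molar/min rates, 1/min gamma).

tf_default:
  kind: tf
  K_A: 140uM
  K_I: 530nM
  eps: 4.5
  n_sites: 2

# Auto-activation switch with strong cooperativity; bistable at
# intermediate effector concentrations (phase-portrait example at c = 25uM).
auto_bistable:
  motif: auto_activation
  params: {r0: 0.1, r1: 1.0, r2: 20.0, omega: 10.0}
  tf: tf_default
  protocol: {kind: constant, c: 25uM}

# Auto-activation set used for relaxation-timescale analysis.
auto_relax:
  motif: auto_activation
  params: {r0: 0.1, r1: 1.0, r2: 20.0, omega: 7.5}
  tf: tf_default
  protocol: {kind: constant, c: 20uM}

# Dimensional parameter sets for the Hill-vs-thermodynamic comparison
# (rates in uM/min, gamma in 1/min, Kd in molar).
hill_compare_low:
  motif: auto_activation_dimensional
  params: {r0: 0.1, r1: 1.0, r2: 2.0, omega: 1.0, gamma: 1.0, Kd: 1uM}
  tf: tf_default
hill_compare_mid:
  motif: auto_activation_dimensional
  params: {r0: 0.1, r1: 1.0, r2: 2.0, omega: 7.5, gamma: 1.0, Kd: 1uM}
  tf: tf_default
hill_compare_high:
  motif: auto_activation_dimensional
  params: {r0: 0.1, r1: 1.0, r2: 2.0, omega: 100.0, gamma: 1.0, Kd: 1uM}
  tf: tf_default

# Symmetric toggle switch (two-effector phase diagram; pitchfork on the
# diagonal).
toggle_symmetric:
  motif: mutual_repression
  params: {rbar: 2.0, omega1: 7.5, omega2: 7.5, Kratio: 1.0}
  tf1: tf_default
  tf2: tf_default
  protocol: {kind: constant, c1: 1uM, c2: 1uM}

# Asymmetric toggle: skewed separatrix and unequal basins.
toggle_asymmetric:
  motif: mutual_repression
  params: {rbar: 2.0, omega1: 50.0, omega2: 7.5, Kratio: 1.0}
  tf1: tf_default
  tf2: tf_default
  protocol: {kind: constant, c1: 5uM, c2: 1uM}

# Coherent feed-forward loop logic gates (Xbar = 1, KXZ = KYZ = 1 unless
# swept).  ffl_or is the worked delayed-response example.
ffl_xor:
  motif: coherent_ffl
  params: {r0Y: 0.0, r1Y: 2.0, r0Z: 0.0, r1Z: 2.0, r2Z: 0.0, omega: 0.0,
           KXZ: 1.0, KYZ: 1.0, Xbar: 1.0}
  tfX: tf_default
  tfY: tf_default
  protocol: &step_protocol {kind: step, cX_high: 1e-4, cX_low: 1e-7, cY: 1e-7}
ffl_and:
  motif: coherent_ffl
  params: {r0Y: 0.0, r1Y: 2.0, r0Z: 0.0, r1Z: 0.0, r2Z: 2.0, omega: 10.0,
           KXZ: 1.0, KYZ: 1.0, Xbar: 1.0}
  tfX: tf_default
  tfY: tf_default
  protocol: *step_protocol
ffl_or:
  motif: coherent_ffl
  params: {r0Y: 0.0, r1Y: 2.0, r0Z: 0.0, r1Z: 2.0, r2Z: 10.0, omega: 1.0,
           KXZ: 1.0, KYZ: 1.0, Xbar: 1.0}
  tfX: tf_default
  tfY: tf_default
  protocol: *step_protocol

# Incoherent feed-forward loop: pulse generation and accelerated response.
iffl_pulse:
  motif: incoherent_ffl
  params: {r0Y: 0.0, r1Y: 2.0, r0Z: 0.0, r1Z: 2.0, omega: 0.0,
           KXZ: 1.0, KYZ: 1.0, Xbar: 1.0}
  tfX: tf_default
  tfY: tf_default
  protocol: *step_protocol
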