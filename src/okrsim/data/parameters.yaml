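# Default physiological parameter set of the cerebellar corticonuclear
# microcomplex model (1 mm^3 of cat cerebellar cortex plus its target
# vestibular nucleus). Units: mV, pF, nS, nA, ms.
schema_version: 1

cells:
  GR:  # granule cell
    theta_spike: -35.0
    C: 3.1
    g_leak: 0.43
    E_leak: -58.0
    g_ampa: 0.18
    g_nmda: 0.025
    E_ex: 0.0
    g_inh: 0.028
    E_inh: -82.0
    g_ahp: 1.0
    E_ahp: -82.0
    tau_ahp: 5.0
    I_ext: null
  GO:  # Golgi cell
    theta_spike: -52.0
    C: 28.0
    g_leak: 2.3
    E_leak: -55.0
    g_ampa: 45.5
    g_nmda: 30.0
    E_ex: 0.0
    g_inh: null
    E_inh: null
    g_ahp: 20.0
    E_ahp: -72.7
    tau_ahp: 5.0
    I_ext: null
  PC:  # Purkinje cell
    theta_spike: -55.0
    C: 107.0
    g_leak: 2.32
    E_leak: -68.0
    g_ampa: 0.7
    g_nmda: null
    E_ex: 0.0
    g_inh: 1.0
    E_inh: -75.0
    g_ahp: 0.1
    E_ahp: -70.0
    tau_ahp: 5.0
    I_ext: 0.25
  BS:  # basket cell
    theta_spike: -55.0
    C: 107.0
    g_leak: 2.32
    E_leak: -68.0
    g_ampa: 0.7
    g_nmda: null
    E_ex: 0.0
    g_inh: null
    E_inh: null
    g_ahp: 0.1
    E_ahp: -70.0
    tau_ahp: 2.5
    I_ext: 0.1
  VN:  # vestibular nucleus neuron
    theta_spike: -38.8
    C: 122.3
    g_leak: 1.63
    E_leak: -56.0
    g_ampa: 50.0
    g_nmda: 25.8
    E_ex: 0.0
    g_inh: 30.0
    E_inh: -88.0
    g_ahp: 50.0
    E_ahp: -70.0
    tau_ahp: 2.5
    I_ext: 0.8
  IO:  # inferior olive neuron
    theta_spike: -50.0
    C: 10.0
    g_leak: 0.67
    E_leak: -60.0
    g_ampa: 1.0
    g_nmda: null
    E_ex: 0.0
    g_inh: 0.18
    E_inh: -75.0
    g_ahp: 1.0
    E_ahp: -75.0
    tau_ahp: 10.0
    I_ext: null

# Synaptic kernels per postsynaptic cell type: lists of [coefficient, tau_ms].
kernels:
  GR:
    ampa: [[1.0, 1.2]]
    nmda: [[1.0, 52.0]]
    gaba: [[0.43, 7.0], [0.57, 59.0]]
  GO:
    ampa: [[1.0, 1.5]]
    nmda: [[0.33, 31.0], [0.67, 170.0]]
  PC:
    ampa: [[1.0, 8.3]]
    gaba: [[1.0, 10.0]]
  BS:
    ampa: [[1.0, 8.3]]
  VN:
    ampa: [[1.0, 9.9]]
    nmda: [[1.0, 30.6]]
    gaba: [[1.0, 42.3]]
  IO:
    ampa: [[1.0, 10.0]]

# Base synaptic weights per pathway (dimensionless multipliers of the
# postsynaptic peak conductance).
weights:
  MF->GR: 4.0
  GO->GR: 10.0
  GR->GO: 4.0e-05
  GR->PC: 0.00075
  GR->BS: 0.00015
  BS->PC: 5.3
  IO->PC: 1.0
  PC->VN: 0.05
  MF->VN: 0.2

# Learning parameters for the two plasticity sites.
#
# The published parameter table lists the pair (0.005, 0.1) for the LTD and
# LTP coefficients of the cortical rule. As labeled, that assignment makes
# the LTP drive exceed the LTD drive by two orders of magnitude under any
# stationary spike statistics, so cortical weights could only rise during
# training. With the two constants in the roles below, the rest state
# (climbing fiber at 1 spikes/s) is exactly stationary:
#   ltp_step_per_spike = ltd_step_per_coincidence * 50 ms * 1 spikes/s,
# independent of the parallel-fiber rate, and training (climbing fiber at
# 1.5 spikes/s, in-phase rate modulation) is net-depressing. We therefore
# treat the table's two entries as transposed relative to their roles.
learning:
  tau_w_min: 20.0
  tau_x_min: 240.0
  ltd_step_per_coincidence: 0.1
  ltp_step_per_spike: 0.005
  ltd_window_ms: 50.0
  mfvn_window_s: 6.0
  w_init: 1.0
  x_init: 0.0
  v_init: 1.0
  w_c: 1.0
  tau_v_days: 3.0
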