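# Fast-spiking inhibitory interneuron: single somatic compartment with fast
# transient-Na and delayed-rectifier currents (no adaptation currents).
# Units: mV, ms, nS, pF, pA.
dt: 2.5e-5
v_init: -67.0
spike_threshold_mv: -20.0
spike_lockout_s: 1.5e-3
kdr_tau_scale: 0.5
compartments:
  soma: {c_pf: 80.0, g_leak_ns: 10.0, e_leak_mv: -70.0}
coupling_ns: []
reversals_mv: {na: 55.0, k: -90.0, ca: 120.0}
channels:
  na_t: {soma: 3000.0}
  k_dr: {soma: 1600.0}
calcium: {phi: 0.0, tau_ca_ms: 200.0, kd: 30.0}
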