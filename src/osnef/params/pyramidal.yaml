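# 4-compartment, 6-current layer-V pyramidal cell (HH-style).
# Units: mV, ms, nS, pF, pA.  Constants are this package's own editable
# parameterization of an intrinsically-bursting/adapting prefrontal pyramidal
# cell; the dopamine-sensitive quantities (na_p threshold shift, k_s and
# ca_hva conductances, synaptic conductance scales) are baked in at one
# constant dopamine level.
dt: 2.5e-5
v_init: -68.0
spike_threshold_mv: -20.0
spike_lockout_s: 2.0e-3
compartments:
  soma:     {c_pf: 120.0, g_leak_ns: 10.0, e_leak_mv: -70.0}
  basal:    {c_pf: 150.0, g_leak_ns: 10.0, e_leak_mv: -70.0}
  proximal: {c_pf: 150.0, g_leak_ns: 10.0, e_leak_mv: -70.0}
  distal:   {c_pf: 180.0, g_leak_ns: 10.0, e_leak_mv: -70.0}
coupling_ns:
  - [soma, basal, 30.0]
  - [soma, proximal, 30.0]
  - [proximal, distal, 15.0]
reversals_mv: {na: 55.0, k: -90.0, ca: 120.0}
channels:
  na_t:   {soma: 3500.0, basal: 120.0, proximal: 120.0, distal: 70.0}
  na_p:   {soma: 15.0,   basal: 8.0,   proximal: 8.0,   distal: 5.0}
  k_dr:   {soma: 1400.0, basal: 80.0,  proximal: 80.0,  distal: 50.0}
  k_s:    {soma: 50.0,   basal: 18.0,  proximal: 18.0,  distal: 12.0}
  ca_hva: {soma: 10.0,   basal: 6.0,   proximal: 6.0,   distal: 4.0}
  k_ca:   {soma: 120.0,  basal: 40.0,  proximal: 40.0,  distal: 30.0}
calcium: {phi: 0.008, tau_ca_ms: 240.0, kd: 30.0}
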