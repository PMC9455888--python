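# Wilson simplified neocortical neuron (three coupled ODEs).
# Voltage is in units of 100 mV; tau_v/tau_r/tau_h in s.
# Spike detection: upward crossing of v_threshold with `lockout` s lockout
# (the ODEs have no hard threshold).
dt: 2.5e-5
tau_v: 0.97e-3
tau_r: 5.6e-3
tau_h: 99.0e-3
v_threshold: -0.20
lockout: 2.0e-3
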