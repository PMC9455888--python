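# Leaky integrate-and-fire (normalized units, spike threshold 1).
# dt: s, tau_rc: s (membrane time constant), tau_ref: s (refractory period).
dt: 1.0e-3
tau_rc: 0.02
tau_ref: 0.002
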