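# Izhikevich quadratic model. The regular-spiking preset is the default;
# other classic presets (intrinsically_bursting, chattering, fast_spiking,
# low_threshold_spiking) are selectable via `preset`.
# dt: s. current_scale converts the incoming drive to model current units.
dt: 1.0e-3
preset: regular_spiking
current_scale: 1.0
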