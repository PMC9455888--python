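# Synapse families for the biologically constrained delayed-response-task
# network.  Time constants are fixed literature values for AMPA, GABA-A and
# NMDA receptor kinetics (s); they are NOT optimized by the filter search.
# Reversal potentials in mV; NMDA magnesium block: 1/(1 + [Mg]/K exp(-gamma V)).
ampa: {tau_rise: 0.5e-3, tau_fall: 2.2e-3, reversal_mv: 0.0}
gaba: {tau_rise: 0.5e-3, tau_fall: 8.0e-3, reversal_mv: -70.0}
nmda: {tau_rise: 10.5e-3, tau_fall: 95.0e-3, reversal_mv: 0.0,
       mg_mm: 1.0, k_mm: 3.57, gamma_per_mv: 0.062}
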