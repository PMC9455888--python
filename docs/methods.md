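# Methods

## The model

This package trains spiking neural networks, built from biophysically
detailed neuron and synapse models, to realize linear dynamical systems

    dx/dt = A x(t) + B u(t)

in a low-dimensional state space represented by the population's spiking.
Representation follows the population-coding scheme of the Neural
Engineering Framework: each neuron i carries a unit preferred-direction
vector (encoder) e_i, a gain and a bias, so its driving current is
J_i = gain_i (e_i · x) + bias_i; a linear readout with decoders d_i
recovers functions of x from spike trains smoothed by the synaptic filter.
Connection weights factor as w_ij = d_i · e_ij, where the per-synapse
encoder tensor e_ij generalizes the usual encoder matrix.

Training is *oracle-supervised*: a parallel, analytically specified stream
filters and transforms the shared input signal and feeds it into a target
population of spiking rectified-linear neurons whose tuning is exact by
construction.  Its smoothed spike activity supervises two online rules,
applied every step:

* encoder rule: Δe_ij = −α_e · sign(d_i) · a_i^pre · (a_j^pop − a_j^tar),
  a Hebbian update gated by the presynaptic decoder's sign and driven by
  the per-neuron activity mismatch with the paired target neuron;
* decoder rule (PES): Δd_i = −(α_d/N) · a_i^pre · (x̂ − x), driven by the
  state-space decode error.

Both rules are implemented with the error-reducing (descent) sign so their
fixed points — activity match and zero decode error — are stable; a config
switch (`printed_sign`) flips the convention for fidelity experiments.

A separate offline procedure optimizes the rise/fall time constants of the
double-exponential readout filter: record spikes under a known input, pick
trial time constants, solve least-squares decoders, score the decode RMSE,
and search (a Parzen-style sequential sampler over log time constants with
a random fallback) for the minimum.  Adaptive neuron models (most visibly
the Wilson model) systematically distort a fixed-filter decode; the
searched filters — typically with a much longer fall time — remove most of
that error.

## Neuron and synapse models

* Spiking ReLU: deterministic integrate-to-threshold generator whose
  time-averaged rate equals max(0, J); the target ("oracle") model.
* LIF: normalized membrane (threshold 1), tau_RC = 20 ms, tau_ref = 2 ms,
  with analytic within-step spike timing so simulated rates match the
  closed-form rate curve within 2% at dt = 1 ms.
* Izhikevich: the classic two-variable quadratic model; regular-spiking
  preset (a=0.02, b=0.2, c=−65, d=8) by default, other presets selectable —
  the operating regime is not pinned down by theory, so it is a config knob.
* Wilson: three coupled ODEs (voltage, conductance, recovery) with cubic
  voltage dynamics, integrated with a midpoint step at dt = 0.025 ms; spike
  detection is an upward crossing of −20 mV with a 2 ms lockout, since the
  ODEs have no hard threshold.
* Pyramidal cell: four compartments (soma, basal, proximal, distal
  dendrites) and six HH-style currents (transient + persistent Na,
  delayed-rectifier, slowly-inactivating and Ca-dependent K, high-voltage
  activated Ca) with an intracellular calcium proxy; constants live in an
  editable parameter file (units documented there) and encode one fixed
  dopamine level.  Gating uses exponential Euler; voltages a semi-implicit
  update, stable at dt = 0.025 ms.  The model is accepted on qualitative
  electrophysiology (quiet rest near −70 mV, repetitive adapting firing
  under steady dendritic conductance, return to rest within 500 ms of
  release), never on matching a particular published voltage trace.
* Fast-spiking interneuron: single-compartment variant of the same
  formalism with fast kinetics and no adaptation currents.

Synapses are double-exponential filters (default 1 ms rise / 100 ms fall)
realized with an impulse-invariant discrete recursion, so stepwise
filtering equals direct convolution with the continuous impulse response to
machine precision.  Three families: current-based (point models),
conductance-based with a reversal potential, and NMDA — a conductance
additionally gated by the Jahr–Stevens magnesium block
1/(1 + [Mg]/3.57 · exp(−0.062 V)).  For compartmental neurons each afferent
synapse is assigned uniformly at random (seeded) to one of the three
dendritic compartments; positive weights deliver excitatory conductance,
negative weights GABA-style inhibitory conductance, since connectivity does
not enforce transmitter-type separation.

## Training signals

Training inputs are band-limited noise built as sums of random-phase
sinusoids below the band limit (1 Hz by default) — exactly band-limited by
construction — affinely rescaled to fill the amplitude range.  For 2-D
*state* trajectories used in recurrent training, plain disk-normalized
noise concentrates at small norms and under-trains the outer region where
stored states live, so the state trajectory instead combines a band-limited
radius profile with a direction-balanced angular sweep plus angular random
walk ("ring coverage").  The angular sweep is symmetric in direction: a net
rotation bias during training would imprint a tangential drift on the
learned map, because activity always lags its target slightly.

The oracle stream mirrors the network stream's synaptic stages: a signal
that reaches the trained population through two synapses is filtered twice
before entering the target population.  A single-stage target would lead
the spikes by a full synaptic lag; at a 1 Hz band limit that is a ~36°
phase bias, enough to destroy a trained rotation.

## Network construction

Feedforward tasks (identity channel, scalar product) are trained exactly as
the two-stage oracle layout prescribes: representation on the first
connection, the function on the second, with presynaptic decoders of the
detailed population solved offline from recorded spikes (ridge least
squares, slope-corrected for ridge shrinkage) and encoder tensors trained
online.  Readout decoders are solved against a lag-fair target: the input
passed through one analytic filter per synaptic stage.

Recurrent tasks are trained on an "unrolled" twin: identical populations
connected feedforward compute the discrete mapping of the dynamics onto the
feedback synapse — for a double-exponential synapse with time constants
t1, t2,

    f_rec(x) = (t1 t2 A² + (t1 + t2) A + I) x,
    g_in(u)  = (t1 t2 A + (t1 + t2) I) B u

— after which the trained weights close the loop.  A small always-on bias
population (n/5 neurons representing the constant 1) is trained into every
recurrent loop: once external input is withdrawn, it carries the constant
component of the drive and keeps activity alive near the origin.

Two lessons from this construction are applied throughout and documented
here because they are genuine design choices:

1. **Initialization of multi-afferent stages.**  When several afferents are
   trained jointly against one summed-current error, only the sum is
   constrained: any apportionment across afferents is a fixed point of the
   encoder rule, so a connection initialized far below its final scale can
   be starved of error credit and deliver an order of magnitude too little
   (the oscillator's kick input, the memory's cue-load path).  Functional
   connections whose presynaptic decoders are already solved therefore
   start at the full composed solution (decoders ⊗ target encoders); online
   training fine-tunes from there.

2. **Closed-loop calibration.**  Least-squares decoders at the 20–40 Hz
   firing rates used here shrink the decoded feedback by 5–25%, and the
   neuron membranes add lag the discretization does not model, so a freshly
   closed loop decays, drifts in frequency, or saturates.  In the spirit of
   the offline simulate-and-minimize filter search, each recurrent builder
   probes its own closed loop and corrects the feedback decoders
   deterministically: the oscillator trim distinguishes oscillating /
   pinned / dead regimes, steering amplitude into the represented range and
   nulling the measured frequency error with a small rotation of the
   decoders; the memory applies a cue-path pre-compensation fitted from
   eight probe loads (the affine map from cue to stored value is inverted
   on the cue decoders).

The gated difference memory (D = 2) uses the difference architecture: the
cue population feeds a difference population, which loads the integrator at
a rate set by `load_gain` (default 4 /s, mapped through the recurrent
synapse's effective time constant); the integrator feeds −x back into the
difference, so loading stops at equilibrium; a gate population silences the
difference with fixed negative weights (scaled to roughly twice the typical
maximal drive) whenever the gate signal is on.  The difference variable
spans up to |cue| + |stored|, so its population uses a radius of 1.5.
Memory populations use 200 neurons ("hundreds" is the architecture's
stated scale); the difference population's representation stage and the
integrator's representation stage are trained with the online rules, their
realized per-neuron encode maps are extracted by an affine fit of the
trained current map over the operating region, and the functional
connections (cue, load, recurrence, feedback) are composed as
decoders ⊗ realized-encode-map with decoders solved under the composed
drive.  This replaces joint online training of the functional stages,
which the apportionment degeneracy above makes unreliable; the module
surface and the factorized-weight contract are unchanged.  The biophysical
variant swaps LIF for pyramidal cells and the gate for fast-spiking
interneurons driven through a trained relay, and assigns synapse classes
per connection: feedforward AMPA, inhibitory GABA, trained
recurrent/feedback NMDA, with time constants fixed to the literature
values in the synapse parameter file — never optimized.

## Delayed-response task

A trial presents a unit-circle cue for 1 s, closes the gate, simulates the
delay, and reads the decoded estimate (200 ms window) into a
winner-take-all cleanup over the eight candidate locations (a mutually
inhibiting LIF network, with an exact argmax oracle mode that it matches
whenever the similarity margin is clear).  A response is correct when the
selected candidate lies within the correctness radius — half the distance
between adjacent cues, i.e. the nearest-neighbor decision region.  Because
the network reports continuously, one simulation to the longest delay
yields the correctness at every grid delay (accuracy as a function of
time, which is also how the forgetting curves are plotted).

The forgetting curve y(t) = B exp(−t/τ) is anchored at the maximum
accuracy in the 0.5–2 s post-cue window (slow synapses keep loading the
attractor after cue offset), τ is fitted by nonlinear least squares on the
later points, B is the anchored curve's value at zero delay capped at 1,
and the half-life is τ ln 2.  Accuracy that never decays yields the +inf
sentinel.  Chance with eight candidates is 1/8 (reporting only).

## Problem sizes and what the tests show

The default test suite runs every model and every topology, at sizes chosen
so the whole suite completes on a single CPU: 100-neuron populations for
the single-population and feedforward/oscillator checks, 200 for the memory,
training signals of 60–250 s at dt = 1 ms, and a reduced-scale "runs
without numeric failure" grid for the slow biophysical models.  The full
biophysical delayed-response experiment (10 network seeds × 8 cues of
multi-second compartmental simulation at dt = 0.025 ms) takes hours and is
run from the command line (`osnef run-drt --surrogate biophysical`), not
from the suite; the suite exercises the same protocol end to end on the
LIF surrogate and smoke-tests the biophysical construction at small size.

Because all inputs are synthetic, passing tests demonstrate that the
training method realizes the target dynamics under the stated tuning
distributions, firing-rate ranges and noise conditions — not that it would
do so for arbitrary biological parameter regimes, real connectomes, or
sensory-statistics inputs.

Known limitations, measured honestly at these scales:

* The trained gated memory stores cue-specific, stable values, but its
  attractor landscape retains per-angle bias beyond what the calibrations
  remove: the mean Euclidean recall error over 10 unit cues and 10 s delays
  is ≈0.5 at n = 200, above the 0.35 replication threshold asserted in the
  acceptance suite (that test is expected to fail and is kept as an honest
  record).
* Desk-scale LIF forgetting curves are steppy (8 cues, deterministic
  trials): some cues never leave their basin within 10 s, so the curve
  flattens above chance and an exponential does not always beat a straight
  line on the tail points.
* The spiking-ReLU target is unbounded; trained neurons match it below
  x ≈ 0.8 and plateau above, which is expected and verified rather than
  fought.

## Numerical choices

* dt = 1 ms for the network loop; Wilson/pyramidal substep at 0.025 ms
  inside it.  Connections carry a one-step transmission delay.
* Ridge regularization defaults to 0.1 of the peak activity (0.05 for
  readouts); lstsq decoders are slope-corrected when the fitted decode
  slope lies in (0.5, 1).
* Learning rates default to α_e = 3e-6, α_d = 2e-6 per step at dt = 1 ms,
  scaled internally by each model's typical drive magnitude and normalized
  by presynaptic count; chosen so single-neuron training converges within
  a few simulated minutes.
* Training divergence is declared when the rolling-mean activity mismatch
  grows tenfold above its (floored) running minimum.
* Degenerate inputs: intercepts ≥ 1 are rejected (undefined gain) and the
  default intercept range tops out at 0.9 — the gain rate/(1 − intercept)
  diverges near 1 and such neurons produce runaway target rates whenever a
  represented value strays past the radius.
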