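"""Double-exponential synaptic filters and the three synapse families.

Every synapse in this package is a second-order lowpass ("double exponential")
filter of presynaptic spikes,

    h(s) = 1 / ((tau_rise s + 1)(tau_fall s + 1)),

whose impulse response has unit area: a single spike through a unit weight
always delivers the same total charge regardless of the time constants.  The
filtered quantity is interpreted three ways:

* ``current``      — delivered directly as input current (point neurons);
* ``conductance``  — a conductance g >= 0; the neuron computes g (E_rev - V);
* ``nmda``         — a conductance additionally scaled by the voltage-dependent
                     magnesium-block factor.

The discrete-time recursion is *impulse invariant*: its impulse response equals
the continuous h sampled on the grid, so stepwise filtering matches direct
convolution to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterParams",
    "impulse_response",
    "peak_time",
    "DoubleExpState",
    "filter_spikes",
    "SynapseSpec",
    "SynapseState",
    "step_synapse",
    "nmda_block",
]

#: Default smoothing / synaptic filter: 1 ms rise, 100 ms fall.
DEFAULT_TAU_RISE = 1e-3
DEFAULT_TAU_FALL = 100e-3


@dataclass(frozen=True)
class FilterParams:
    """Rise and fall time constants of a double-exponential filter (seconds).

    Construction swap-normalizes so that ``tau_rise <= tau_fall``; the filter
    is symmetric in its two poles so (a, b) and (b, a) denote the same filter.
    """

    tau_rise: float = DEFAULT_TAU_RISE
    tau_fall: float = DEFAULT_TAU_FALL

    def __post_init__(self):
        tr, tf = float(self.tau_rise), float(self.tau_fall)
        if not (np.isfinite(tr) and np.isfinite(tf)) or tr <= 0 or tf <= 0:
            raise ValueError("time constants must be positive and finite")
        if tr > tf:
            tr, tf = tf, tr
        object.__setattr__(self, "tau_rise", tr)
        object.__setattr__(self, "tau_fall", tf)

    @property
    def is_confluent(self) -> bool:
        return np.isclose(self.tau_rise, self.tau_fall)


def impulse_response(filt: FilterParams, t) -> np.ndarray:
    """h(t) of the double-exponential filter, units 1/s; t >= 0.

    h(t) = (exp(-t/tau_fall) - exp(-t/tau_rise)) / (tau_fall - tau_rise),
    with the confluent (alpha-synapse) limit (t/tau^2) exp(-t/tau) when the
    two time constants coincide.  The integral of h over [0, inf) is 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("impulse response is causal: t must be >= 0")
    tr, tf = filt.tau_rise, filt.tau_fall
    if filt.is_confluent:
        tau = 0.5 * (tr + tf)
        return (t / tau**2) * np.exp(-t / tau)
    return (np.exp(-t / tf) - np.exp(-t / tr)) / (tf - tr)


def peak_time(filt: FilterParams) -> float:
    """Closed-form maximizer of h: t* = ln(tf/tr) tr tf / (tf - tr)."""
    tr, tf = filt.tau_rise, filt.tau_fall
    if filt.is_confluent:
        return 0.5 * (tr + tf)
    return float(np.log(tf / tr) * tr * tf / (tf - tr))


class DoubleExpState:
    """Impulse-invariant state-space realization of the filter for n channels.

    Two internal first-order states per channel.  ``step`` consumes the spike
    (or arbitrary impulse-weighted) input for one step and returns the filtered
    trace sampled at the *end* of the step, in Hz for unit-area spike inputs.
    """

    def __init__(self, filt: FilterParams, n: int, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.filt = filt
        self.dt = float(dt)
        self.n = int(n)
        tr, tf = filt.tau_rise, filt.tau_fall
        self._confluent = filt.is_confluent
        if self._confluent:
            tau = 0.5 * (tr + tf)
            self._a = np.exp(-dt / tau)
            self._tau = tau
            self._p = np.zeros(n)  # sum of a^(k-j) x_j
            self._r = np.zeros(n)  # sum of (k-j) dt a^(k-j) x_j
        else:
            self._af = np.exp(-dt / tf)
            self._ar = np.exp(-dt / tr)
            self._scale = 1.0 / (tf - tr)
            self._p = np.zeros(n)
            self._q = np.zeros(n)

    def copy(self) -> "DoubleExpState":
        new = DoubleExpState(self.filt, self.n, self.dt)
        if self._confluent:
            new._p[:] = self._p
            new._r[:] = self._r
        else:
            new._p[:] = self._p
            new._q[:] = self._q
        return new

    def step(self, spikes: np.ndarray) -> np.ndarray:
        """Advance one step with ``spikes`` (count per channel this step)."""
        x = np.asarray(spikes, dtype=float)
        if self._confluent:
            self._r = self._a * (self._r + self.dt * self._p)
            self._p = self._a * self._p + x
            return self._r / self._tau**2
        self._p = self._af * self._p + x
        self._q = self._ar * self._q + x
        return (self._p - self._q) * self._scale

    @property
    def output(self) -> np.ndarray:
        if self._confluent:
            return self._r / self._tau**2
        return (self._p - self._q) * self._scale


def filter_spikes(spikes, filt: FilterParams, dt: float, duration: float) -> np.ndarray:
    """Smooth spike trains into activity traces a_i(t) = sum_T h(t - T), Hz.

    Parameters
    ----------
    spikes : ndarray (T, n) of per-step spike counts, or sequence of
        per-neuron spike-time arrays (seconds, within [0, duration]).
    filt : FilterParams
    dt, duration : float

    Returns
    -------
    ndarray (T, n) — causal filtered activities on the sample grid.
    """
    n_steps = int(round(duration / dt))
    raster = _as_raster(spikes, dt, n_steps)
    state = DoubleExpState(filt, raster.shape[1], dt)
    out = np.empty_like(raster, dtype=float)
    for k in range(n_steps):
        out[k] = state.step(raster[k])
    return out


def _as_raster(spikes, dt: float, n_steps: int) -> np.ndarray:
    arr = np.asarray(spikes, dtype=object) if isinstance(spikes, (list, tuple)) else spikes
    if isinstance(arr, np.ndarray) and arr.dtype != object and arr.ndim == 2:
        if arr.shape[0] != n_steps:
            raise ValueError("raster length disagrees with duration/dt")
        return arr.astype(float)
    # sequence of spike-time arrays
    trains = spikes if isinstance(spikes, (list, tuple)) else [spikes]
    raster = np.zeros((n_steps, len(trains)))
    for i, times in enumerate(trains):
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            continue
        if times.min() < 0 or times.max() > n_steps * dt + 1e-12:
            raise ValueError("spike times outside [0, duration]")
        idx = np.minimum((times / dt).astype(int), n_steps - 1)
        np.add.at(raster[:, i], idx, 1.0)
    return raster


# ---------------------------------------------------------------------------
# Synapse families


# Jahr–Stevens-style magnesium block; constants follow the usual
# 1 / (1 + [Mg]/K * exp(-gamma V)) convention with V in mV.
NMDA_MG_MM = 1.0
NMDA_K_MM = 3.57
NMDA_GAMMA_PER_MV = 0.062


def nmda_block(v_mv, mg_mm: float = NMDA_MG_MM, k_mm: float = NMDA_K_MM, gamma: float = NMDA_GAMMA_PER_MV):
    """Voltage-dependent NMDA magnesium-block factor, in (0, 1).

    Strictly increasing in V; near zero at hyperpolarized potentials.
    """
    v = np.asarray(v_mv, dtype=float)
    return 1.0 / (1.0 + (mg_mm / k_mm) * np.exp(-gamma * v))


@dataclass(frozen=True)
class SynapseSpec:
    """What kind of synapse a connection uses and where it lands.

    ``current`` delivers filtered weighted spikes as input current (nA-scale,
    in the receiving model's normalized units).  ``conductance`` delivers a
    non-negative conductance toward ``reversal_potential`` (mV).  ``nmda`` is
    a conductance additionally gated by the magnesium block.
    """

    kind: str = "current"  # current | conductance | nmda
    filter: FilterParams = field(default_factory=FilterParams)
    reversal_potential: float | None = None  # mV; conductance kinds only
    target_compartment: str | None = None  # compartmental neurons only
    mg_concentration: float | None = None  # mM; nmda only

    def __post_init__(self):
        if self.kind not in ("current", "conductance", "nmda"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.kind == "current" and self.reversal_potential is not None:
            raise ValueError("current synapses have no reversal potential")
        if self.kind in ("conductance", "nmda") and self.reversal_potential is None:
            object.__setattr__(self, "reversal_potential", 0.0)
        if self.kind == "nmda":
            mg = NMDA_MG_MM if self.mg_concentration is None else self.mg_concentration
            if mg <= 0:
                raise ValueError("nmda requires mg_concentration > 0")
            object.__setattr__(self, "mg_concentration", float(mg))


class SynapseState:
    """Filter state for one (pre-population -> post-target) channel bundle."""

    def __init__(self, spec: SynapseSpec, n: int, dt: float):
        self.spec = spec
        self.state = DoubleExpState(spec.filter, n, dt)


def step_synapse(spec: SynapseSpec, state: SynapseState, weighted_input: np.ndarray, post_voltage=None, dt: float | None = None):
    """Advance a synapse one step; return (state, delivered drive).

    ``weighted_input`` is the per-channel weighted spike input for this step
    (weight times spike count).  For ``current``, the return is the delivered
    current.  For conductance kinds the return is a conductance (>= 0); NMDA
    additionally requires the postsynaptic voltage each step and scales by the
    magnesium block.
    """
    filtered = state.state.step(np.asarray(weighted_input, dtype=float))
    if spec.kind == "current":
        return state, filtered
    g = filtered
    if np.any(g < -1e-9):
        raise RuntimeError("conductance synapse produced negative conductance")
    g = np.maximum(g, 0.0)
    if spec.kind == "nmda":
        if post_voltage is None:
            raise ValueError("nmda synapse requires post_voltage every step")
        g = g * nmda_block(post_voltage, mg_mm=spec.mg_concentration)
    return state, g
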