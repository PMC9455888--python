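"""Time-stepped spiking neuron models behind one uniform step contract.

Six models are provided, in increasing order of biophysical detail:

* ``relu_spiking`` — deterministic integrate-to-threshold rate neuron whose
  time-averaged spike rate equals a rectified-linear function of its drive.
  Used as the *target* ("oracle") tuning model.
* ``lif``          — leaky integrate-and-fire in normalized units (threshold 1)
  with exact within-step spike-time handling, so simulated rates match the
  closed-form rate curve.
* ``izhikevich``   — two-variable quadratic model; the regular-spiking preset
  is the default, other classic presets are selectable.
* ``wilson``       — three coupled ODEs (voltage, conductance, recovery) with
  cubic voltage dynamics; produces genuine action potentials, adaptation and
  bursting.  Requires a small timestep.
* ``pyramidal``    — a 4-compartment (soma, basal, proximal and distal
  dendrites), 6-current (2 Na, 3 K, 1 Ca) Hodgkin-Huxley-style layer-V
  pyramidal cell with an intracellular calcium proxy, driven by conductances
  attached to named compartments.
* ``interneuron``  — single-compartment fast-spiking inhibitory cell using the
  same channel formalism.

Point models take input *current* (model units); compartmental models take
per-compartment, per-class *conductances*.  All models emit at most one spike
per neuron per step and honor their reset/refractory semantics.  Constants for
the biophysical models live in editable parameter files under ``params/``
(units documented there); acceptance of those models is on qualitative
electrophysiology, never on matching a particular published voltage trace.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "NeuronParams",
    "create",
    "step",
    "lif_rate",
    "SpikingReLU",
    "LIF",
    "Izhikevich",
    "Wilson",
    "Compartmental",
    "spikes_to_table",
    "IZHIKEVICH_PRESETS",
]

MODEL_KINDS = ("relu_spiking", "lif", "izhikevich", "wilson", "pyramidal", "interneuron")

#: Classic parameter presets for the Izhikevich model (a, b, c, d).
IZHIKEVICH_PRESETS = {
    "regular_spiking": dict(a=0.02, b=0.2, c=-65.0, d=8.0),
    "intrinsically_bursting": dict(a=0.02, b=0.2, c=-55.0, d=4.0),
    "chattering": dict(a=0.02, b=0.2, c=-50.0, d=2.0),
    "fast_spiking": dict(a=0.1, b=0.2, c=-65.0, d=2.0),
    "low_threshold_spiking": dict(a=0.02, b=0.25, c=-65.0, d=2.0),
}


def _load_param_file(name: str) -> dict:
    ref = importlib.resources.files("osnef").joinpath(f"params/{name}.yaml")
    with ref.open("r") as f:
        return yaml.safe_load(f)


@dataclass
class NeuronParams:
    """Model kind, timestep and the named scalar constants of one model."""

    model_kind: str
    dt: float
    model_constants: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def create(kind: str, n: int, dt: float | None = None, **overrides):
    """Instantiate ``n`` neurons of one model kind with file-backed defaults."""
    if kind == "relu_spiking":
        return SpikingReLU(n, dt=dt or 1e-3)
    if kind == "lif":
        cfg = _load_param_file("lif")
        cfg.update(overrides)
        file_dt = cfg.pop("dt", 1e-3)
        return LIF(n, dt=dt or file_dt, **cfg)
    if kind == "izhikevich":
        cfg = _load_param_file("izhikevich")
        preset = overrides.pop("preset", cfg.pop("preset", "regular_spiking"))
        consts = dict(IZHIKEVICH_PRESETS[preset])
        consts["current_scale"] = cfg.pop("current_scale", 1.0)
        consts.update(overrides)
        file_dt = cfg.pop("dt", 1e-3)
        return Izhikevich(n, dt=dt or file_dt, **consts)
    if kind == "wilson":
        cfg = _load_param_file("wilson")
        cfg.update(overrides)
        file_dt = cfg.pop("dt", 2.5e-5)
        return Wilson(n, dt=dt or file_dt, **cfg)
    if kind in ("pyramidal", "interneuron"):
        cfg = _load_param_file(kind)
        cfg.update(overrides)
        file_dt = cfg.pop("dt", 2.5e-5)
        return Compartmental(n, kind=kind, dt=dt or file_dt, config=cfg)
    raise ValueError(f"unknown model kind {kind!r}")


def step(model, drive, dt: float | None = None) -> np.ndarray:
    """Uniform step contract: advance ``model`` one step under ``drive``.

    ``drive`` is a per-neuron current array for point models, or a mapping of
    compartment name to a list of (conductance nS, reversal mV) pairs for
    compartmental models.  Returns the spike indicator (0/1 per neuron).
    """
    return model.step(drive, dt=dt)


def _check_dt(model, dt: float | None) -> float:
    dt = model.dt if dt is None else float(dt)
    if dt > model.max_stable_dt:
        raise ValueError(
            f"{model.kind}: dt={dt:g}s exceeds the stability bound {model.max_stable_dt:g}s"
        )
    return dt


def _check_finite(drive) -> np.ndarray:
    drive = np.asarray(drive, dtype=float)
    if not np.all(np.isfinite(drive)):
        raise ValueError("non-finite drive rejected")
    return drive


class SpikingReLU:
    """Deterministic integrate-to-threshold spike generation from a ReLU rate.

    The drive is interpreted as an instantaneous rate in Hz (already rectified
    upstream or rectified here); an internal accumulator increases by rate*dt
    and a spike is emitted (accumulator decremented by 1) on reaching 1, so
    over any window the spike count is floor/ceil of the integrated rate.
    """

    kind = "relu_spiking"
    max_stable_dt = np.inf
    drive_kind = "current"
    drive_scale = 30.0  # rate-like units: a drive of ~30 means ~30 Hz

    def __init__(self, n: int, dt: float = 1e-3):
        self.n = int(n)
        self.dt = float(dt)
        self.reset()

    def reset(self):
        self.accumulator = np.zeros(self.n)

    def step(self, drive, dt: float | None = None) -> np.ndarray:
        dt = self.dt if dt is None else float(dt)
        rate = np.maximum(_check_finite(drive), 0.0)
        self.accumulator += rate * dt
        spikes = (self.accumulator >= 1.0).astype(float)
        self.accumulator -= spikes
        if np.any(self.accumulator < -1e-12):
            raise RuntimeError("spiking-ReLU accumulator went negative (invariant breach)")
        return spikes


def lif_rate(J, tau_rc: float = 0.02, tau_ref: float = 0.002) -> np.ndarray:
    """Closed-form LIF steady rate for normalized current J (threshold 1)."""
    J = np.asarray(J, dtype=float)
    out = np.zeros_like(J)
    above = J > 1.0
    out[above] = 1.0 / (tau_ref + tau_rc * np.log1p(1.0 / (J[above] - 1.0)))
    return out


class LIF:
    """Leaky integrate-and-fire, normalized voltage in [0, 1], threshold 1.

    Within-step spike times and partial refractory periods are resolved
    analytically, so long-run simulated rates track the closed-form rate curve
    even at a 1 ms timestep.
    """

    kind = "lif"
    max_stable_dt = 0.01
    drive_kind = "current"
    drive_scale = 1.3  # normalized current for rates in the tens of Hz

    def __init__(self, n: int, dt: float = 1e-3, tau_rc: float = 0.02, tau_ref: float = 0.002):
        if tau_rc <= 0 or tau_ref < 0:
            raise ValueError("tau_rc must be > 0 and tau_ref >= 0")
        self.n = int(n)
        self.dt = float(dt)
        self.tau_rc = float(tau_rc)
        self.tau_ref = float(tau_ref)
        self.reset()

    def reset(self):
        self.voltage = np.zeros(self.n)
        self.refractory = np.zeros(self.n)

    def step(self, drive, dt: float | None = None) -> np.ndarray:
        dt = _check_dt(self, dt)
        J = _check_finite(drive)
        self.refractory -= dt
        delta_t = np.clip(dt - self.refractory, 0.0, dt)
        self.voltage = J + (self.voltage - J) * np.exp(-delta_t / self.tau_rc)
        spiked = self.voltage > 1.0
        spikes = spiked.astype(float)
        if np.any(spiked):
            # time left in the step after threshold crossing
            overshoot = (self.voltage[spiked] - 1.0) / (J[spiked] - 1.0)
            t_spike = dt + self.tau_rc * np.log1p(-overshoot)
            self.refractory[spiked] = self.tau_ref + t_spike
            self.voltage[spiked] = 0.0
        np.maximum(self.voltage, 0.0, out=self.voltage)
        return spikes


class Izhikevich:
    """Two-variable quadratic model; v in mV, u is the recovery variable."""

    kind = "izhikevich"
    max_stable_dt = 2e-3
    drive_kind = "current"
    drive_scale = 12.0

    def __init__(self, n: int, dt: float = 1e-3, a: float = 0.02, b: float = 0.2,
                 c: float = -65.0, d: float = 8.0, current_scale: float = 1.0):
        self.n = int(n)
        self.dt = float(dt)
        self.a, self.b, self.c, self.d = a, b, c, d
        self.current_scale = current_scale
        self.reset()

    def reset(self):
        self.v = np.full(self.n, self.c)
        self.u = self.b * self.v

    def step(self, drive, dt: float | None = None) -> np.ndarray:
        dt = _check_dt(self, dt)
        I = _check_finite(drive) * self.current_scale
        spikes = np.zeros(self.n)
        n_sub = max(1, int(round(dt / 2.5e-4)))
        h = dt / n_sub * 1e3  # model time unit is ms
        for _ in range(n_sub):
            dv = 0.04 * self.v**2 + 5.0 * self.v + 140.0 - self.u + I
            self.v = self.v + h * dv
            self.u = self.u + h * self.a * (self.b * self.v - self.u)
            fired = self.v >= 30.0
            if np.any(fired):
                spikes[fired] = 1.0  # at most one spike per (outer) step
                self.v[fired] = self.c
                self.u[fired] += self.d
        return spikes


class Wilson:
    """Wilson's simplified neocortical neuron: three coupled ODEs.

    State is voltage V (units of 100 mV), a fast conductance-like recovery R,
    and a slow after-hyperpolarization variable H.  The cubic voltage dynamics
    generate genuine action potentials with adaptation; spikes are detected as
    upward crossings of the detection threshold with a short lockout, since
    the ODEs have no hard threshold.
    """

    kind = "wilson"
    max_stable_dt = 1e-4
    drive_kind = "current"
    drive_scale = 0.8

    def __init__(self, n: int, dt: float = 2.5e-5, tau_v: float = 0.97e-3,
                 tau_r: float = 5.6e-3, tau_h: float = 99.0e-3,
                 v_threshold: float = -0.20, lockout: float = 2e-3):
        self.n = int(n)
        self.dt = float(dt)
        self.tau_v, self.tau_r, self.tau_h = tau_v, tau_r, tau_h
        self.v_threshold = v_threshold
        self.lockout = lockout
        self.reset()

    def reset(self):
        self.V = np.full(self.n, -0.754)
        self.R = np.full(self.n, 0.279)
        self.H = np.zeros(self.n)
        self._since_spike = np.full(self.n, 1e9)

    def rhs(self, V, R, H, J):
        dV = (-(17.81 + 47.58 * V + 33.8 * V**2) * (V - 0.48)
              - 26.0 * R * (V + 0.95) - 13.0 * H * (V + 0.95) + J) / self.tau_v
        dR = (-R + 1.29 * V + 0.79 + 3.3 * (V + 0.38) ** 2) / self.tau_r
        dH = (-H + 11.0 * (V + 0.754) * (V + 0.69)) / self.tau_h
        return dV, dR, dH

    def step(self, drive, dt: float | None = None) -> np.ndarray:
        dt = _check_dt(self, dt)
        J = _check_finite(drive)
        v_prev = self.V.copy()
        # midpoint (RK2) integration: the cubic dynamics are stiff near spikes
        dV1, dR1, dH1 = self.rhs(self.V, self.R, self.H, J)
        Vm = self.V + 0.5 * dt * dV1
        Rm = self.R + 0.5 * dt * dR1
        Hm = self.H + 0.5 * dt * dH1
        dV2, dR2, dH2 = self.rhs(Vm, Rm, Hm, J)
        self.V = self.V + dt * dV2
        self.R = self.R + dt * dR2
        self.H = self.H + dt * dH2
        self._since_spike += dt
        crossed = (v_prev < self.v_threshold) & (self.V >= self.v_threshold)
        spikes = (crossed & (self._since_spike > self.lockout)).astype(float)
        self._since_spike[spikes > 0] = 0.0
        return spikes


# ---------------------------------------------------------------------------
# Compartmental Hodgkin-Huxley-style models (pyramidal cell, interneuron)


def _sigmoid(v, mid, slope):
    return 1.0 / (1.0 + np.exp(-(v - mid) / slope))


class Compartmental:
    """Multi-compartment HH-style neuron driven by dendritic conductances.

    Voltages are in mV, time internally in ms, conductances in nS,
    capacitances in pF, currents in pA.  Channel gating uses
    steady-state/time-constant kinetics advanced with exponential Euler;
    voltages use a semi-implicit update that treats each compartment's own
    conductances implicitly (stable at the default 0.025 ms timestep).

    The pyramidal configuration has exactly four compartments (soma, basal,
    proximal, distal) and six ionic currents: transient and persistent Na,
    delayed-rectifier, slowly-inactivating and Ca-dependent K, and a
    high-voltage-activated Ca current feeding an intracellular Ca proxy.
    """

    max_stable_dt = 5e-5
    drive_kind = "conductance"
    drive_scale = 15.0  # nS of excitatory conductance for moderate firing

    def __init__(self, n: int, kind: str, dt: float, config: dict):
        self.kind = kind
        self.n = int(n)
        self.dt = float(dt)
        self.cfg = config
        self.comp_names = list(config["compartments"].keys())
        nc = len(self.comp_names)
        if kind == "pyramidal" and nc != 4:
            raise ValueError("pyramidal model requires exactly 4 compartments")
        self._comp_index = {name: i for i, name in enumerate(self.comp_names)}
        self.C = np.array([config["compartments"][c]["c_pf"] for c in self.comp_names])
        self.gL = np.array([config["compartments"][c]["g_leak_ns"] for c in self.comp_names])
        self.EL = np.array([config["compartments"][c]["e_leak_mv"] for c in self.comp_names])
        self.E = config["reversals_mv"]
        self.channels = config["channels"]
        if kind == "pyramidal" and len(self.channels) != 6:
            raise ValueError("pyramidal model requires exactly 6 ionic currents")
        self.gbar = {
            ch: np.array([dens.get(c, 0.0) for c in self.comp_names])
            for ch, dens in self.channels.items()
        }
        self.ca_cfg = config.get("calcium", {"phi": 0.0, "tau_ca_ms": 200.0, "kd": 30.0})
        # axial coupling matrix (nS between named compartments)
        self.g_axial = np.zeros((nc, nc))
        for a, b, g in config.get("coupling_ns", []):
            ia, ib = self._comp_index[a], self._comp_index[b]
            self.g_axial[ia, ib] = g
            self.g_axial[ib, ia] = g
        self.v_threshold = config.get("spike_threshold_mv", -20.0)
        self.lockout = config.get("spike_lockout_s", 2e-3)
        self.v_init = config.get("v_init", -66.0)
        self.reset()

    def reset(self):
        n, nc = self.n, len(self.comp_names)
        self.V = np.full((n, nc), float(self.v_init))
        v = self.V
        self.gates = {}
        if "na_t" in self.gbar:
            self.gates["na_t_h"] = _sigmoid(-v, 50.0, 6.5)  # h_inf(v)
        if "na_p" in self.gbar:
            self.gates["na_p_p"] = _sigmoid(v, -45.0, 4.0)
        if "k_dr" in self.gbar:
            self.gates["k_dr_n"] = _sigmoid(v, -30.0, 9.0)
        if "k_s" in self.gbar:
            self.gates["k_s_a"] = _sigmoid(v, -34.0, 6.5)
            self.gates["k_s_b"] = _sigmoid(-v, 65.0, 6.6)
        if "ca_hva" in self.gbar:
            self.gates["ca_q"] = _sigmoid(v, -10.0, 6.0)
        self.Ca = np.zeros((n, nc))
        self._since_spike = np.full(n, 1e9)

    def voltage(self, compartment: str = "soma") -> np.ndarray:
        return self.V[:, self._comp_index[compartment]]

    def _exp_gate(self, key, inf, tau_ms, dt_ms):
        g = self.gates[key]
        self.gates[key] = inf + (g - inf) * np.exp(-dt_ms / tau_ms)

    def step(self, drive=None, dt: float | None = None, i_inj_pa=None) -> np.ndarray:
        """Advance one step.

        ``drive`` maps compartment name -> iterable of (g_nS, E_mV) pairs
        (per-neuron conductance arrays or scalars).  ``i_inj_pa`` optionally
        injects current at the soma (testing convenience).
        """
        dt = _check_dt(self, dt)
        dt_ms = dt * 1e3
        v = self.V
        E_na, E_k, E_ca = self.E["na"], self.E["k"], self.E["ca"]

        # --- gating kinetics (exponential Euler; tau in ms) ---
        if "na_t_h" in self.gates:
            tau_h = 0.35 + 4.0 * _sigmoid(-v, 46.0, 4.0)
            self._exp_gate("na_t_h", _sigmoid(-v, 50.0, 6.5), tau_h, dt_ms)
        if "na_p_p" in self.gates:
            self._exp_gate("na_p_p", _sigmoid(v, -45.0, 4.0), 1.0, dt_ms)
        if "k_dr_n" in self.gates:
            tau_n = 0.6 + 4.0 * _sigmoid(-v, 25.0, 10.0) * self.cfg.get("kdr_tau_scale", 1.0)
            self._exp_gate("k_dr_n", _sigmoid(v, -30.0, 9.0), tau_n, dt_ms)
        if "k_s_a" in self.gates:
            self._exp_gate("k_s_a", _sigmoid(v, -34.0, 6.5), 6.0, dt_ms)
            self._exp_gate("k_s_b", _sigmoid(-v, 65.0, 6.6), 220.0, dt_ms)
        if "ca_q" in self.gates:
            self._exp_gate("ca_q", _sigmoid(v, -10.0, 6.0), 1.5, dt_ms)

        # --- total conductance and reversal-weighted drive per compartment ---
        g_tot = np.broadcast_to(self.gL, v.shape).copy()
        gE_tot = np.broadcast_to(self.gL * self.EL, v.shape).copy()

        def add_channel(gbar, gate, E_rev):
            g = gbar[None, :] * gate
            nonlocal g_tot, gE_tot
            g_tot = g_tot + g
            gE_tot = gE_tot + g * E_rev

        i_ca = np.zeros_like(v)
        if "na_t" in self.gbar:
            m_inf = _sigmoid(v, -33.0, 5.5)
            add_channel(self.gbar["na_t"], m_inf**3 * self.gates["na_t_h"], E_na)
        if "na_p" in self.gbar:
            add_channel(self.gbar["na_p"], self.gates["na_p_p"], E_na)
        if "k_dr" in self.gbar:
            add_channel(self.gbar["k_dr"], self.gates["k_dr_n"] ** 4, E_k)
        if "k_s" in self.gbar:
            add_channel(self.gbar["k_s"], self.gates["k_s_a"] * self.gates["k_s_b"], E_k)
        if "ca_hva" in self.gbar:
            g_ca = self.gbar["ca_hva"][None, :] * self.gates["ca_q"] ** 2
            g_tot = g_tot + g_ca
            gE_tot = gE_tot + g_ca * E_ca
            i_ca = g_ca * (v - E_ca)  # pA, negative = inward
        if "k_ca" in self.gbar:
            kd = self.ca_cfg["kd"]
            add_channel(self.gbar["k_ca"], self.Ca / (self.Ca + kd), E_k)

        # --- synaptic conductances ---
        if drive:
            for comp, pairs in drive.items():
                ci = self._comp_index[comp]
                for g_syn, E_syn in pairs:
                    g_syn = np.asarray(g_syn, dtype=float)
                    if np.any(g_syn < 0):
                        raise ValueError("synaptic conductance must be >= 0")
                    g_tot[:, ci] = g_tot[:, ci] + g_syn
                    gE_tot[:, ci] = gE_tot[:, ci] + g_syn * E_syn

        inj = np.zeros_like(v)
        if i_inj_pa is not None:
            inj[:, self._comp_index["soma"]] = np.asarray(i_inj_pa, dtype=float)

        # --- semi-implicit voltage update (own conductances implicit,
        #     axial neighbor terms explicit) ---
        axial_in = v @ self.g_axial.T  # sum_j g_ij V_j
        axial_g = self.g_axial.sum(axis=1)  # sum_j g_ij
        a = dt_ms / self.C[None, :]
        v_new = (v + a * (gE_tot + axial_in + inj)) / (1.0 + a * (g_tot + axial_g))
        v_prev_soma = v[:, self._comp_index["soma"]].copy()
        self.V = v_new

        # --- calcium proxy ---
        phi, tau_ca = self.ca_cfg["phi"], self.ca_cfg["tau_ca_ms"]
        if phi:
            self.Ca = np.maximum(self.Ca + dt_ms * (-phi * i_ca - self.Ca / tau_ca), 0.0)

        self._since_spike += dt
        soma = self.V[:, self._comp_index["soma"]]
        crossed = (v_prev_soma < self.v_threshold) & (soma >= self.v_threshold)
        spikes = (crossed & (self._since_spike > self.lockout)).astype(float)
        self._since_spike[spikes > 0] = 0.0
        return spikes


def spikes_to_table(raster: np.ndarray, dt: float):
    """Convert a (T, n) spike raster into a (neuron_id, spike_time_s) table."""
    import pandas as pd

    steps, neurons = np.nonzero(np.asarray(raster) > 0)
    return pd.DataFrame({"neuron_id": neurons, "spike_time_s": steps * dt}).sort_values(
        ["neuron_id", "spike_time_s"], ignore_index=True
    )
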