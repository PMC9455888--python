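"""Oracle-supervised online training of factorized synaptic weights.

Training runs two streams side by side on a shared input signal.  The oracle
stream filters and transforms the signal analytically and feeds it into a
target population ("tar") of spiking rectified-linear neurons whose tuning is
specified by standard NEF means; its filtered spike activity is the
supervision signal.  The network stream drives the population under training
("pop") through weighted synapses from one or more presynaptic sources; the
weights factor into presynaptic decoders and a per-synapse encoder tensor.

Two online rules update the factors every step, on activities smoothed with
the synaptic filter:

* the encoder rule nudges each synapse's encoder in proportion to the
  presynaptic activity and the (postsynaptic - target) activity mismatch,
  gated by the sign of the presynaptic decoder — Hebbian in form, supervised
  through the oracle;
* the PES rule nudges presynaptic decoders along the state-space decode error.

Both rules are applied with the error-*reducing* (descent) sign so their fixed
points (activity match, zero decode error) are stable; a switch restores the
opposite sign convention for fidelity experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .encoding import Connection, Decoders, Population, solve_decoders
from .signals import Signal, bandlimited_noise
from .synapses import DoubleExpState, FilterParams, SynapseSpec, nmda_block

logger = logging.getLogger(__name__)

__all__ = [
    "LearningConfig",
    "OracleStream",
    "SourceSpec",
    "TrainingDivergence",
    "encoder_update",
    "pes_update",
    "train_population",
    "train_connections",
]

#: Mean of the default maximum-rate range; used to convert rate-unit encoder
#: geometry into model drive units.
_RATE_SCALE = 30.0


class TrainingDivergence(RuntimeError):
    """Raised when the activity mismatch grows 10x from its running minimum."""

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log


@dataclass
class LearningConfig:
    """Learning rates, training signal and bookkeeping for online training.

    ``alpha_e``/``alpha_d`` are per-step rates at dt = 1 ms (scaled internally
    by each model's typical drive magnitude so one setting serves models whose
    input currents live on different scales).  The training signal is smoothed
    band-limited white noise filling [-1, 1].
    """

    alpha_e: float = 3e-6
    alpha_d: float = 2e-6
    duration: float = 100.0
    band_limit_hz: float = 1.0
    signal_seed: int = 0
    dt: float = 1e-3
    filter: FilterParams = field(default_factory=FilterParams)
    update_interval: int = 1
    log_interval: float = 1.0
    printed_sign: bool = False
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.alpha_e < 0 or self.alpha_d < 0:
            raise ValueError("learning rates must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class OracleStream:
    """The analytically specified supervision stream.

    ``tar`` is a spiking-ReLU population with the desired tuning distribution;
    it is driven by NEF encoding of the analytically transformed (and
    synaptically filtered) input, so its activities are guaranteed to realize
    the target tuning curves.
    """

    tar: Population
    transform: Callable[[np.ndarray], np.ndarray] = lambda x: x
    filter: FilterParams = field(default_factory=FilterParams)


def encoder_update(d_pre: np.ndarray, a_pre: np.ndarray, a_pop: np.ndarray,
                   a_tar: np.ndarray, alpha_e: float, printed_sign: bool = False) -> np.ndarray:
    """Per-synapse encoder update from the spike-space activity mismatch.

    Returns the (n_pre, n_post, D) tensor increment
    ``-alpha_e sign(d_i) a_i (a_j - a_k)`` (descent convention; ``sign(0)=0``;
    target neuron k is paired one-to-one with postsynaptic neuron j).  The
    update vanishes when activities match or the presynaptic neuron is silent.
    """
    d_pre = np.atleast_2d(np.asarray(d_pre, dtype=float))
    a_pre = np.asarray(a_pre, dtype=float)
    a_pop = np.asarray(a_pop, dtype=float)
    a_tar = np.asarray(a_tar, dtype=float)
    if np.any(a_pre < 0) or np.any(a_pop < 0) or np.any(a_tar < 0):
        raise ValueError("activities must be non-negative (smoothed spike traces)")
    sign = -1.0 if not printed_sign else 1.0
    err = a_pop - a_tar
    return sign * alpha_e * np.sign(d_pre)[:, None, :] * a_pre[:, None, None] * err[None, :, None]


def pes_update(a_pre: np.ndarray, x_hat: np.ndarray, x: np.ndarray,
               alpha_d: float, n_pre: int, printed_sign: bool = False) -> np.ndarray:
    """PES decoder update: ``-(alpha_d / N) a_i (x_hat - x)`` (descent form)."""
    a_pre = np.asarray(a_pre, dtype=float)
    err = np.atleast_1d(np.asarray(x_hat, dtype=float) - np.asarray(x, dtype=float))
    sign = -1.0 if not printed_sign else 1.0
    return sign * (alpha_d / n_pre) * np.outer(a_pre, err)


@dataclass
class SourceSpec:
    """One presynaptic stream feeding the population under training.

    ``pop`` is an NEF-parameterized population (spiking ReLU or LIF) driven
    directly by ``signal``; alternatively ``scaffold`` supplies previously
    trained connections — each paired with the drive signal for its own NEF
    presynaptic population — letting a detailed population act as the source
    (the "unrolled" twin used for recurrent targets).  In the scaffolded case
    ``signal`` is the value the source *represents*, used for decoder targets.

    ``function`` maps the synaptically filtered source signal to this source's
    contribution to the postsynaptic state; contributions of all sources sum.
    ``decoder_mode`` selects how presynaptic decoders are found: online PES,
    offline least squares on recorded activities, or fixed.
    """

    pop: Population
    signal: np.ndarray
    function: Callable[[np.ndarray], np.ndarray] = lambda x: x
    decoder_mode: str = "pes"  # pes | lstsq | fixed
    decoders: Decoders | None = None
    scaffold: Sequence[tuple[Connection, np.ndarray]] | None = None
    synapse: SynapseSpec | None = None
    name: str = "pre"
    #: initial encoder tensor (default: scaled target-encoder initialization)
    encoder_init: np.ndarray | None = None
    #: per-source override of the encoder initialization scale (1.0 starts at
    #: the standard NEF outer-product weights; None uses the config default)
    init_scale: float | None = None
    #: frozen sources deliver their drive but receive no updates; used to
    #: carry an already-trained connection (e.g. the bias) into a later stage
    trainable: bool = True

    @classmethod
    def frozen(cls, connection: Connection, signal: np.ndarray, d_out: int,
               name: str = "frozen") -> "SourceSpec":
        return cls(pop=connection.pre, signal=signal,
                   function=lambda y, d=d_out: np.zeros(d),
                   decoder_mode="fixed", decoders=connection.decoders,
                   synapse=connection.synapse,
                   encoder_init=np.array(connection.encoder_tensor),
                   trainable=False, name=name)


# ---------------------------------------------------------------------------
# runtime helpers


class _NeuronRunner:
    """Steps a neuron model at its own dt inside a coarser loop step."""

    def __init__(self, pop: Population, loop_dt: float):
        self.pop = pop
        self.model = pop.make_neurons()
        self.model_dt = min(self.model.dt, loop_dt)
        self.n_sub = max(1, int(round(loop_dt / self.model_dt)))
        self.conductance = self.model.drive_kind == "conductance"

    def reset(self):
        self.model.reset()

    def step(self, drive) -> np.ndarray:
        if self.n_sub == 1:
            return self.model.step(drive, dt=self.model_dt)
        spikes = np.zeros(self.model.n)
        for _ in range(self.n_sub):
            spikes += self.model.step(drive, dt=self.model_dt)
        return np.minimum(spikes, 1.0)


#: dendritic compartments among which afferent synapses are distributed
DENDRITIC_COMPARTMENTS = ("basal", "proximal", "distal")
E_EXC_MV = 0.0
E_INH_MV = -70.0


class _DriveAssembler:
    """Turns weighted filtered activity into the drive a model accepts.

    Point models receive the summed weighted activity as current.  For
    compartmental models each (pre, post) synapse is assigned uniformly at
    random to one of the three dendritic compartments (seeded); positive
    weights deliver excitatory conductance (optionally voltage-gated NMDA),
    negative weights deliver GABA-style inhibitory conductance.
    """

    def __init__(self, runner: _NeuronRunner, n_pre: int, seed: int = 0,
                 synapse: SynapseSpec | None = None):
        self.runner = runner
        self.synapse = synapse
        if runner.conductance:
            rng = np.random.default_rng(seed)
            comps = [c for c in DENDRITIC_COMPARTMENTS if c in runner.model._comp_index]
            if not comps:
                comps = ["soma"]
            assign = rng.integers(0, len(comps), size=(n_pre, runner.model.n))
            self.masks = {c: (assign == k).astype(float) for k, c in enumerate(comps)}

    def drive(self, a_pre: np.ndarray, w: np.ndarray):
        if not self.runner.conductance:
            return a_pre @ w
        model = self.runner.model
        nmda = self.synapse is not None and self.synapse.kind == "nmda"
        out = {}
        for comp, mask in self.masks.items():
            wm = w * mask
            g_exc = a_pre @ np.maximum(wm, 0.0)
            g_inh = a_pre @ np.maximum(-wm, 0.0)
            pairs = []
            if nmda:
                v = model.voltage(comp)
                e_rev = self.synapse.reversal_potential
                pairs.append((g_exc * nmda_block(v, mg_mm=self.synapse.mg_concentration), e_rev))
            else:
                e_rev = E_EXC_MV if self.synapse is None else (self.synapse.reversal_potential
                                                               if self.synapse.kind == "conductance" else E_EXC_MV)
                pairs.append((g_exc, e_rev))
            pairs.append((g_inh, E_INH_MV))
            out[comp] = pairs
        return out

    @staticmethod
    def merge(drives):
        """Sum a list of compartmental drive dicts."""
        merged: dict = {}
        for d in drives:
            for comp, pairs in d.items():
                merged.setdefault(comp, []).extend(pairs)
        return merged


class _SourceRuntime:
    """Simulates one presynaptic stream and maintains its filtered activity."""

    def __init__(self, spec: SourceSpec, cfg: LearningConfig, syn_filter: FilterParams):
        self.spec = spec
        self.signal = np.atleast_2d(np.asarray(spec.signal, dtype=float))
        self.runner = _NeuronRunner(spec.pop, cfg.dt)
        self.a_filter = DoubleExpState(syn_filter, spec.pop.n, cfg.dt)
        # the oracle stream mirrors the network stream's synaptic stages: a
        # directly driven source carries one filter stage; a scaffolded source
        # adds the scaffold synapse's filter, so target and activity stay
        # time-aligned (a one-stage target would lead the spikes by a full
        # synaptic lag and bias the decoders)
        dims_sig = self.signal.shape[1]
        self.sig_filters = [DoubleExpState(syn_filter, dims_sig, cfg.dt)]
        if spec.scaffold:
            sc_filter = spec.scaffold[0][0].synapse.filter
            self.sig_filters.insert(0, DoubleExpState(sc_filter, dims_sig, cfg.dt))
        self.scaffold = spec.scaffold
        if self.scaffold is not None:
            self._sc = []
            for conn, sig in self.scaffold:
                entry = {
                    "conn": conn,
                    "filter": DoubleExpState(conn.synapse.filter, conn.pre.n, cfg.dt),
                    "weights": conn.weights,
                    "assembler": _DriveAssembler(self.runner, conn.pre.n, seed=cfg.seed,
                                                 synapse=conn.synapse),
                }
                if isinstance(sig, SourceSpec):
                    # nested scaffold: the afferent's own presynaptic population
                    # is detailed and must itself be driven through trained
                    # connections (mirrors the full training-network layout)
                    entry["sub"] = _SourceRuntime(sig, cfg, conn.synapse.filter)
                else:
                    entry["signal"] = np.atleast_2d(np.asarray(sig, dtype=float))
                    entry["runner"] = _NeuronRunner(conn.pre, cfg.dt)
                self._sc.append(entry)
        self.a = np.zeros(spec.pop.n)
        self.y_filtered = np.zeros(self.signal.shape[1])

    def step(self, k: int) -> None:
        x = self.signal[k]
        # the filter recursion consumes per-step impulse areas; a continuous
        # signal sample enters as x*dt so the output tracks h * x
        y = x
        for f in self.sig_filters:
            y = f.step(y * f.dt)
        self.y_filtered = y
        if self.scaffold is None:
            J = self.spec.pop.current(x)
            spikes = self.runner.step(J)
        else:
            drives = []
            for sc in self._sc:
                if "sub" in sc:
                    sc["sub"].step(k)
                    a_pre = sc["filter"].step(sc["sub"]._last_spikes)
                else:
                    u = sc["signal"][min(k, sc["signal"].shape[0] - 1)]
                    a_pre = sc["filter"].step(sc["runner"].step(sc["conn"].pre.current(u)))
                drives.append(sc["assembler"].drive(a_pre, sc["weights"]))
            if self.runner.conductance:
                spikes = self.runner.step(_DriveAssembler.merge(drives))
            else:
                spikes = self.runner.step(sum(drives))
        self._last_spikes = spikes
        self.a = self.a_filter.step(spikes)


def train_population(pre: Population, pop: Population, oracle: OracleStream,
                     cfg: LearningConfig):
    """Train one connection so ``pop`` realizes the oracle's target tuning.

    Runs the oracle and network streams on a shared band-limited noise signal,
    applying the encoder rule and (for NEF-compatible sources) PES online.
    Returns ``(connection, log)`` where the log is a per-interval table of the
    activity mismatch and decode RMSE.
    """
    signal = bandlimited_noise(cfg.band_limit_hz, cfg.duration, cfg.dt,
                               dims=pre.dims, seed=cfg.signal_seed)
    source = SourceSpec(pop=pre, signal=signal.values, function=oracle.transform,
                        decoder_mode="pes", name="pre")
    conns, log = train_connections([source], pop, oracle, cfg)
    return conns[0], log


def _init_decoders(spec: SourceSpec, cfg: LearningConfig, d_out: int) -> np.ndarray:
    if spec.decoders is not None:
        return np.array(spec.decoders.d, dtype=float)
    pop = spec.pop
    if pop.kind in ("relu_spiking", "lif"):
        # analytic least squares on the closed-form tuning curves
        rng = np.random.default_rng(cfg.seed + 17)
        grid = rng.uniform(-1.0, 1.0, size=(400, pop.dims))
        if pop.dims > 1:
            norm = np.linalg.norm(grid, axis=1, keepdims=True)
            grid = np.where(norm > 1.0, grid / norm, grid)
        A = pop.rates(grid)
        Y = np.atleast_2d(np.asarray(spec.function(grid), dtype=float))
        if Y.shape[0] != grid.shape[0]:
            Y = Y.T
        return solve_decoders(A, Y).d
    return np.zeros((pop.n, d_out))


def train_connections(sources: Sequence[SourceSpec], post: Population,
                      oracle: OracleStream, cfg: LearningConfig):
    """Jointly train the connections from several sources into ``post``.

    The oracle target state is the sum of every source's transformed
    (filtered) signal; training all afferents of a population together lets
    the rules apportion the target bias current across connections instead of
    multiply counting it.  Sources with ``decoder_mode='lstsq'`` get their
    presynaptic decoders from a recording pre-pass (offline least squares on
    filtered spikes); PES sources are updated online.
    """
    cfg_filter = cfg.filter
    tar = oracle.tar
    if tar.n != post.n:
        raise ValueError("oracle target population must pair one-to-one with post")
    n_steps = min(np.atleast_2d(np.asarray(s.signal)).shape[0] for s in sources)
    dt = cfg.dt

    runtimes = [_SourceRuntime(s, cfg, s.synapse.filter if s.synapse else cfg_filter)
                for s in sources]

    # ------------------------------------------------------------------ decoders
    needs_prepass = any(s.decoder_mode == "lstsq" for s in sources)
    if needs_prepass:
        rec_a = {i: [] for i, s in enumerate(sources) if s.decoder_mode == "lstsq"}
        rec_y = {i: [] for i in rec_a}
        for k in range(n_steps):
            for i, rt in enumerate(runtimes):
                rt.step(k)
                if i in rec_a and k % 5 == 0 and k * dt > 4 * cfg_filter.tau_fall:
                    rec_a[i].append(rt.a.copy())
                    rec_y[i].append(np.atleast_1d(rt.spec.function(rt.y_filtered)))
        for i in rec_a:
            A = np.array(rec_a[i])
            Y = np.array(rec_y[i])
            d = solve_decoders(A, Y)
            # ridge regression shrinks the decode; rescale so the decoded
            # projection onto the target has unit slope (matters most in
            # recurrent loops, where shrinkage compounds every pass)
            x_hat = A @ d.d
            denom = float(np.sum(Y * Y))
            if denom > 0:
                slope = float(np.sum(x_hat * Y) / denom)
                # cap the amplification: a tiny slope signals a poor fit, not
                # shrinkage worth inverting
                if 0.5 < slope < 1.0:
                    d.d /= slope
            sources[i].decoders = d
        for rt in runtimes:
            rt.__init__(rt.spec, cfg, rt.spec.synapse.filter if rt.spec.synapse else cfg_filter)

    d_out = post.dims
    decoders = [_init_decoders(s, cfg, d_out) for s in sources]

    # ------------------------------------------------------------------ encoders
    rng = np.random.default_rng(cfg.seed)
    post_runner = _NeuronRunner(post, dt)
    drive_scale = post_runner.model.drive_scale
    e_target = (drive_scale / _RATE_SCALE) * post.gain[:, None] * post.encoders  # (n_post, D)
    e_tensors = []
    for s in sources:
        if s.encoder_init is not None:
            e_tensors.append(np.array(s.encoder_init, dtype=float))
            continue
        base = np.broadcast_to(e_target[None, :, :], (s.pop.n, post.n, post.dims)).copy()
        noise = rng.normal(scale=0.1, size=base.shape) * np.abs(base).mean()
        scale = cfg.init_scale if s.init_scale is None else s.init_scale
        e_tensors.append(scale * (base + noise))

    assemblers = [_DriveAssembler(post_runner, s.pop.n, seed=cfg.seed + 101 + i,
                                  synapse=s.synapse) for i, s in enumerate(sources)]

    tar_runner = _NeuronRunner(tar, dt)
    a_post_f = DoubleExpState(cfg_filter, post.n, dt)
    a_tar_f = DoubleExpState(cfg_filter, tar.n, dt)

    # normalize per presynaptic count: the summed drive change per step grows
    # with the number of afferents, so the raw rate destabilizes large sources
    alpha_e_eff = [cfg.alpha_e * drive_scale * (100.0 / s.pop.n) for s in sources]
    log_every = max(1, int(round(cfg.log_interval / dt)))
    log_rows = []
    err_a_acc = 0.0
    err_x_acc = 0.0
    acc_n = 0
    min_mismatch = np.inf

    weights = [np.einsum("id,ijd->ij", decoders[i], e_tensors[i]) for i in range(len(sources))]

    for k in range(n_steps):
        y_total = np.zeros(post.dims)
        for i, rt in enumerate(runtimes):
            rt.step(k)
            y_total = y_total + np.atleast_1d(rt.spec.function(rt.y_filtered))

        # network stream: weighted, filtered spikes drive the trained population
        if post_runner.conductance:
            drive = _DriveAssembler.merge(
                [assemblers[i].drive(runtimes[i].a, weights[i]) for i in range(len(sources))])
        else:
            drive = sum(runtimes[i].a @ weights[i] for i in range(len(sources)))
        post_spikes = post_runner.step(drive)
        a_post = a_post_f.step(post_spikes)

        # oracle stream: analytic transform -> target population spikes
        J_tar = tar.current(y_total)
        a_tar = a_tar_f.step(tar_runner.step(J_tar))

        err_activity = a_post - a_tar
        x_err_norm = 0.0
        if cfg.alpha_e > 0 or cfg.alpha_d > 0:
            for i, rt in enumerate(runtimes):
                if not rt.spec.trainable:
                    continue
                if cfg.alpha_e > 0:
                    e_tensors[i] += encoder_update(decoders[i], rt.a, a_post, a_tar,
                                                   alpha_e_eff[i], cfg.printed_sign)
                if cfg.alpha_d > 0 and rt.spec.decoder_mode == "pes":
                    y_i = np.atleast_1d(rt.spec.function(rt.y_filtered))
                    x_hat = rt.a @ decoders[i]
                    decoders[i] += pes_update(rt.a, x_hat, y_i, cfg.alpha_d,
                                              rt.spec.pop.n, cfg.printed_sign)
                    x_err_norm += float(np.sum((x_hat - y_i) ** 2))
                weights[i] = np.einsum("id,ijd->ij", decoders[i], e_tensors[i])

        err_a_acc += float(np.mean(err_activity**2))
        err_x_acc += x_err_norm
        acc_n += 1
        if (k + 1) % log_every == 0:
            mismatch = float(np.sqrt(err_a_acc / acc_n))
            decode_rmse = float(np.sqrt(err_x_acc / acc_n))
            log_rows.append({"t": (k + 1) * dt, "activity_rmse": mismatch,
                             "decode_rmse": decode_rmse})
            logger.debug("train t=%.1fs activity_rmse=%.3f decode_rmse=%.4f",
                         (k + 1) * dt, mismatch, decode_rmse)
            err_a_acc = err_x_acc = 0.0
            acc_n = 0
            if (k + 1) * dt > 5 * cfg_filter.tau_fall:
                # divergence check on a rolling mean (single-interval spikes at
                # rarely visited state extremes recover by themselves), with a
                # floored minimum so a transiently silent network is not
                # mistaken for a diverged one
                recent = float(np.mean([r["activity_rmse"] for r in log_rows[-5:]]))
                min_mismatch = min(min_mismatch, max(recent, 2.0))
                if recent > 10.0 * min_mismatch:
                    raise TrainingDivergence(
                        f"activity mismatch {recent:.2f} grew 10x from its minimum "
                        f"{min_mismatch:.2f}", log=log_rows)

    import pandas as pd

    log = pd.DataFrame(log_rows)
    conns = []
    for i, s in enumerate(sources):
        conns.append(Connection(
            pre=s.pop, post=post,
            decoders=Decoders(d=decoders[i], function=getattr(s.function, "__name__", "f")),
            encoder_tensor=e_tensors[i],
            synapse=s.synapse or SynapseSpec(kind="current", filter=cfg_filter),
            function=s.name,
        ))
    return conns, log
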