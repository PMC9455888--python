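"""NEF state-space machinery: tuning curves, encoding, decoding, weights.

A population of n neurons represents a D-dimensional state x through
heterogeneous tuning curves.  Each neuron i has a unit-norm preferred
direction (encoder) e_i, a gain and a bias; its driving current is
J_i = gain_i (e_i . x) + bias_i.  Target tuning curves are rectified-linear:
a neuron is parameterized by the x-intercept at which it starts firing and
the maximum rate it reaches at the edge of the represented range.  Linear
decoders d_i recover functions of x from filtered spike activity, and
connection weights factor into decoders and encoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .neurons import create as create_neurons, lif_rate

__all__ = [
    "TuningDistribution",
    "Population",
    "Decoders",
    "Connection",
    "sample_tuning",
    "encode_current",
    "decode_state",
    "solve_decoders",
    "compose_weights",
    "empirical_tuning",
    "sample_encoders",
]

#: Regularization default: assumes decode noise ~10% of the maximum rate.
DEFAULT_RIDGE = 0.1


@dataclass
class TuningDistribution:
    """Distribution from which a population's tuning curves are sampled.

    x-intercepts are uniform over ``x_intercept_range`` (values where a neuron
    stops firing along its preferred direction), maximum rates uniform over
    ``max_rate_range`` (Hz, attained at the edge of the represented range),
    encoders unit vectors.  The intercept range tops out slightly below the
    edge of the space: the gain max_rate/(1 - intercept) diverges as the
    intercept approaches 1, and such neurons produce runaway target rates the
    moment a represented value strays past the radius.
    """

    n: int
    dims: int = 1
    x_intercept_range: tuple[float, float] = (-1.0, 0.9)
    max_rate_range: tuple[float, float] = (20.0, 40.0)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.x_intercept_range
        if not lo < hi:
            raise ValueError("x_intercept_range must be non-degenerate")
        if hi >= 1.0 - 1e-9 and hi > 1.0:
            raise ValueError("x-intercepts >= 1 leave the gain undefined")
        rlo, rhi = self.max_rate_range
        if not (0 < rlo < rhi):
            raise ValueError("max_rate_range must be positive and non-degenerate")


def sample_encoders(n: int, dims: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm preferred directions: ±1 in 1-D, uniform on the sphere else."""
    if dims == 1:
        return rng.choice([-1.0, 1.0], size=(n, 1))
    e = rng.normal(size=(n, dims))
    if dims == 2:
        theta = rng.uniform(0, 2 * np.pi, size=n)
        e = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        return e
    return e / np.linalg.norm(e, axis=1, keepdims=True)


@dataclass
class Population:
    """n neurons of one model kind plus their NEF tuning parameterization.

    ``gain`` and ``bias`` realize the sampled x-intercepts and maximum rates
    exactly for the rectified-linear target model (and, through the rate
    curve, for the LIF); detailed models carry the *target* parameterization
    their trained synapses should reproduce.
    """

    kind: str
    n: int
    dims: int
    encoders: np.ndarray  # (n, D), unit norm
    gain: np.ndarray  # (n,)
    bias: np.ndarray  # (n,)
    x_intercepts: np.ndarray
    max_rates: np.ndarray
    neuron_options: dict = field(default_factory=dict)
    radius: float = 1.0  # represented range: currents encode x / radius

    def current(self, x: np.ndarray) -> np.ndarray:
        """J_i = gain_i (e_i . x) + bias_i for one state vector or a batch."""
        return encode_current(x, self)

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Closed-form steady rates at state x (relu and lif kinds only)."""
        J = self.current(x)
        if self.kind == "relu_spiking":
            return np.maximum(J, 0.0)
        if self.kind == "lif":
            tau_rc = self.neuron_options.get("tau_rc", 0.02)
            tau_ref = self.neuron_options.get("tau_ref", 0.002)
            return lif_rate(J, tau_rc, tau_ref)
        raise ValueError(f"no closed-form rate curve for kind {self.kind!r}")

    def make_neurons(self, dt: float | None = None):
        return create_neurons(self.kind, self.n, dt=dt, **self.neuron_options)


def sample_tuning(dist: TuningDistribution, kind: str = "relu_spiking", radius: float = 1.0,
                  **neuron_options) -> Population:
    """Sample a population's encoders, gains and biases from a distribution.

    For the rectified-linear model the geometry along each neuron's preferred
    direction gives gain = max_rate / (1 - x_intercept) and
    bias = -gain * x_intercept, so rate(x_intercept) = 0 and rate at the far
    edge equals the sampled maximum exactly.  For the LIF the same two
    constraints are solved through the closed-form rate curve.  Reproducible
    under the distribution's seed.
    """
    rng = np.random.default_rng(dist.seed)
    e = sample_encoders(dist.n, dist.dims, rng)
    x_int = rng.uniform(*dist.x_intercept_range, size=dist.n)
    rates = rng.uniform(*dist.max_rate_range, size=dist.n)
    if np.any(x_int >= 1.0):
        raise ValueError("x-intercepts >= 1 leave the gain undefined")
    if kind in ("relu_spiking",) or kind not in ("lif",):
        gain = rates / (1.0 - x_int)
        bias = -gain * x_int
    else:  # lif: solve gain/bias so J(x_int) = 1 (threshold) and rate(1) = max
        tau_rc = neuron_options.get("tau_rc", 0.02)
        tau_ref = neuron_options.get("tau_ref", 0.002)
        j_max = 1.0 + 1.0 / np.expm1((1.0 / rates - tau_ref) / tau_rc)
        gain = (j_max - 1.0) / (1.0 - x_int)
        bias = 1.0 - gain * x_int
    return Population(
        kind=kind, n=dist.n, dims=dist.dims, encoders=e, gain=gain, bias=bias,
        x_intercepts=x_int, max_rates=rates, neuron_options=neuron_options, radius=radius,
    )


def encode_current(x: np.ndarray, pop: Population) -> np.ndarray:
    """Current into each neuron for state x: J = gain (E x) + bias.

    ``x`` may be a single D-vector or a (T, D) batch; the result is (n,) or
    (T, n) accordingly.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("state must be finite")
    squeeze = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != pop.dims:
        raise ValueError(f"state dimension {x2.shape[1]} != population dims {pop.dims}")
    J = pop.gain[None, :] * ((x2 / pop.radius) @ pop.encoders.T) + pop.bias[None, :]
    return J[0] if squeeze else J


@dataclass
class Decoders:
    """Linear readout weights for a named function f: d is (n, D_out)."""

    d: np.ndarray
    function: str = "identity"

    def __post_init__(self):
        self.d = np.atleast_2d(np.asarray(self.d, dtype=float))
        if self.d.ndim != 2:
            raise ValueError("decoders must be (n, D)")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("decoders must be finite")


def decode_state(activity: np.ndarray, d) -> np.ndarray:
    """x_hat(t) = sum_i a_i(t) d_i.  ``activity`` is (T, n) or (n,)."""
    dm = d.d if isinstance(d, Decoders) else np.atleast_2d(np.asarray(d, dtype=float))
    a = np.asarray(activity, dtype=float)
    if a.ndim == 1:
        return a @ dm
    if a.shape[1] != dm.shape[0]:
        raise ValueError("activity and decoder shapes disagree")
    return a @ dm


def solve_decoders(activity: np.ndarray, targets: np.ndarray, ridge: float = DEFAULT_RIDGE,
                   function: str = "f") -> Decoders:
    """Regularized least-squares decoders minimizing ||A d - f||^2.

    ``ridge`` is a regularization fraction: the penalty is
    (ridge * max|A|)^2 * m on the squared decoder norm (m = sample count),
    matching the assumption of decode noise proportional to the peak rate.
    Deterministic; rejects an all-silent population.
    """
    A = np.atleast_2d(np.asarray(activity, dtype=float))
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if A.shape[0] != Y.shape[0]:
        raise ValueError("activity and target sample counts disagree")
    a_max = np.abs(A).max()
    if a_max == 0:
        raise ValueError("all neurons silent over the sample grid: cannot solve decoders")
    m = A.shape[0]
    sigma = ridge * a_max
    if sigma == 0:
        d = np.linalg.lstsq(A, Y, rcond=None)[0]  # min-norm solution
    else:
        G = A.T @ A + m * sigma**2 * np.eye(A.shape[1])
        d = np.linalg.solve(G, A.T @ Y)
    return Decoders(d=d, function=function)


def compose_weights(d, e) -> np.ndarray:
    """Compose factorized weights w_ij = d_i . e_ij.

    ``e`` may be an (n_post, D) encoder *matrix* (the standard NEF outer
    product w = d e^T) or an (n_pre, n_post, D) encoder *tensor* with one
    D-vector per synapse, the form the online encoder rule operates on.
    """
    dm = d.d if isinstance(d, Decoders) else np.asarray(d, dtype=float)
    dm = np.atleast_2d(dm)
    e = np.asarray(e, dtype=float)
    if e.ndim == 2:
        if e.shape[1] != dm.shape[1]:
            raise ValueError("decoder/encoder state dimensions disagree")
        return dm @ e.T
    if e.ndim == 3:
        if e.shape[0] != dm.shape[0] or e.shape[2] != dm.shape[1]:
            raise ValueError("decoder/encoder tensor shapes disagree")
        return np.einsum("id,ijd->ij", dm, e)
    raise ValueError("encoders must be a matrix or a tensor")


def empirical_tuning(x_trace: np.ndarray, activity: np.ndarray, n_bins: int = 21,
                     x_range: tuple[float, float] = (-1.0, 1.0)):
    """Binned empirical tuning curve: mean activity and 95% band per state bin.

    The state space is divided into ``n_bins`` equal regions; every activity
    sample is associated with the bin of its concurrent state value.  The
    reported interval is the 95% variability band of the smoothed activity
    within the bin (mean ± 1.96 std): spiking neurons show natural rate
    variation at any given state value, and the band quantifies it.  Empty
    bins are reported as NaN (missing), never as zero.

    Returns
    -------
    centers, mean, ci_half : ndarrays of length n_bins
        Bin centers, per-bin mean activity and the band half-width.
    """
    x = np.asarray(x_trace, dtype=float).reshape(-1)
    a = np.asarray(activity, dtype=float).reshape(-1)
    if x.shape[0] != a.shape[0]:
        raise ValueError("traces must be time-aligned")
    edges = np.linspace(x_range[0], x_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    ci = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = a[idx == b]
        if vals.size == 0:
            continue
        mean[b] = vals.mean()
        ci[b] = 1.96 * vals.std(ddof=1) if vals.size > 1 else 0.0
    return centers, mean, ci


@dataclass
class Connection:
    """A trained connection: factorized weights plus a synapse specification.

    The composed weight matrix always equals ``compose_weights`` of the stored
    factors; the encoder tensor form is used wherever online learning was
    applied.
    """

    pre: Population
    post: Population
    decoders: Decoders  # presynaptic decoders (n_pre, D)
    encoder_tensor: np.ndarray  # (n_pre, n_post, D)
    synapse: object  # SynapseSpec
    function: str = "identity"

    @property
    def weights(self) -> np.ndarray:
        return compose_weights(self.decoders, self.encoder_tensor)

    def with_decoders(self, d: Decoders) -> "Connection":
        return replace(self, decoders=d)
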