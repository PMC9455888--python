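"""State-space input signals and shared error metrics.

Networks in this package are driven by low-dimensional, time-sampled state
signals.  Training and evaluation both use smoothed band-limited white noise;
task protocols use square cue pulses on the unit circle.  All generators are
seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Signal",
    "bandlimited_noise",
    "cue_signal",
    "step_signal",
    "rmse",
    "derive_seeds",
]


@dataclass
class Signal:
    """A time-sampled trajectory of a D-dimensional state vector.

    Attributes
    ----------
    dt : float
        Sample interval in seconds (constant across the trace).
    values : ndarray, shape (T, D)
        Sampled state values.
    meta : dict
        Generator provenance (band limit, seed, amplitude range, ...).
    """

    dt: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("Signal values must be a (T, D) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Signal values must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def dims(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent component seeds from one master seed.

    Uses a splittable counter scheme (``numpy.random.SeedSequence``) so that
    adding components never perturbs the seeds of existing ones.  Returned
    seeds are 31-bit non-negative integers.
    """
    ss = np.random.SeedSequence(int(master_seed))
    return [int(child.generate_state(1, dtype=np.uint32)[0] % (2**31)) for child in ss.spawn(n)]


def bandlimited_noise(
    limit_hz: float,
    duration: float,
    dt: float,
    dims: int = 1,
    seed: int = 0,
    amplitude: tuple[float, float] = (-1.0, 1.0),
) -> Signal:
    """Smoothed band-limited white noise.

    The signal is a sum of sinusoids at the harmonics of ``1/duration`` up to
    ``limit_hz``, with independent Rayleigh amplitudes and uniform phases per
    component and per dimension, then rescaled so each dimension exactly fills
    the requested amplitude range.  Summing random-phase sinusoids keeps the
    spectrum *exactly* band limited, which is the property the generator is
    named for (a lowpass-filtered white noise would only be approximately so).

    Parameters
    ----------
    limit_hz : float
        Highest frequency present.  Must be below Nyquist (``1 / (2 dt)``).
    duration, dt : float
        Trace length and sample interval, seconds.
    dims : int
        Number of independent dimensions.
    seed : int
        RNG seed; identical seeds give identical signals.
    amplitude : (low, high)
        Each dimension is affinely rescaled so min == low and max == high.
    """
    nyquist = 0.5 / dt
    if limit_hz >= nyquist:
        raise ValueError(f"band limit {limit_hz} Hz must be below Nyquist ({nyquist:.1f} Hz)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    f0 = 1.0 / duration
    n_comp = max(1, int(np.floor(limit_hz / f0)))
    freqs = f0 * np.arange(1, n_comp + 1)

    values = np.zeros((n_steps, dims))
    for d in range(dims):
        amps = rng.rayleigh(scale=1.0, size=n_comp)
        phases = rng.uniform(0, 2 * np.pi, size=n_comp)
        x = (amps[None, :] * np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])).sum(axis=1)
        lo, hi = x.min(), x.max()
        if hi - lo < 1e-12:
            x = np.zeros_like(x)
        else:
            x = (x - lo) / (hi - lo) * (amplitude[1] - amplitude[0]) + amplitude[0]
        values[:, d] = x
    return Signal(
        dt=dt,
        values=values,
        meta={"kind": "bandlimited_noise", "limit_hz": limit_hz, "seed": seed, "amplitude": tuple(amplitude)},
    )


def cue_signal(angle: float, on_duration: float, total: float, dt: float) -> Signal:
    """A 2-D unit-norm cue ``(cos angle, sin angle)`` presented then removed.

    The cue is held for ``on_duration`` seconds and is exactly zero afterwards,
    matching the presentation protocol of the delayed-response task.
    """
    if on_duration > total:
        raise ValueError("on_duration must not exceed total")
    n_steps = int(round(total / dt))
    n_on = int(round(on_duration / dt))
    values = np.zeros((n_steps, 2))
    values[:n_on, 0] = np.cos(angle)
    values[:n_on, 1] = np.sin(angle)
    return Signal(dt=dt, values=values, meta={"kind": "cue", "angle": angle, "on_duration": on_duration})


def step_signal(amplitude: np.ndarray, on_duration: float, total: float, dt: float) -> Signal:
    """A square pulse of ``amplitude`` (D-vector) for ``on_duration`` seconds."""
    amplitude = np.atleast_1d(np.asarray(amplitude, dtype=float))
    n_steps = int(round(total / dt))
    n_on = int(round(on_duration / dt))
    values = np.zeros((n_steps, amplitude.size))
    values[:n_on] = amplitude
    return Signal(dt=dt, values=values, meta={"kind": "step", "on_duration": on_duration})


def rmse(estimate, target, dt: float | None = None, warmup: float = 0.0) -> float:
    """Root-mean-square of the pointwise Euclidean error between two traces.

    Parameters
    ----------
    estimate, target : Signal or ndarray (T, D)
        Time-aligned traces of equal length.
    dt : float, optional
        Required (from either argument or explicitly) when ``warmup > 0``.
    warmup : float
        Initial stretch, in seconds, discarded before averaging (filter
        transients bias the error estimate otherwise).
    """
    if isinstance(estimate, Signal):
        dt = dt or estimate.dt
        estimate = estimate.values
    if isinstance(target, Signal):
        dt = dt or target.dt
        target = target.values
    estimate = np.atleast_2d(np.asarray(estimate, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if estimate.shape[0] == 1 and estimate.shape[1] > 1:  # row vector from atleast_2d on 1-D input
        estimate = estimate.T
    if target.shape[0] == 1 and target.shape[1] > 1:
        target = target.T
    if estimate.shape != target.shape:
        raise ValueError(f"trace shapes disagree: {estimate.shape} vs {target.shape}")
    start = 0
    if warmup > 0:
        if dt is None:
            raise ValueError("dt required when warmup > 0")
        start = int(round(warmup / dt))
        if start >= estimate.shape[0]:
            raise ValueError("warmup longer than trace")
    err = estimate[start:] - target[start:]
    return float(np.sqrt(np.mean(np.sum(err**2, axis=1))))
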