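"""Three-neuron continuous-time recurrent network: parameter types and integration.

The network follows leaky-integrator dynamics

    tau_i dy_i/dt = -y_i + sum_j w_{j->i} sigma(y_j + theta_j)

with neuron labels ``LP``, ``PY`` and ``PD`` and output
``o_i = sigma(y_i + theta_i)`` bounded in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from ._kernels import rk4_record

NEURONS = ("LP", "PY", "PD")
N_IDX = {n: i for i, n in enumerate(NEURONS)}

TAU_RANGE = (0.1, 2.0)
BIAS_RANGE = (-16.0, 16.0)
DEFAULT_WEIGHT_RANGE = (-16.0, 16.0)

__all__ = [
    "NEURONS",
    "N_IDX",
    "TAU_RANGE",
    "BIAS_RANGE",
    "DEFAULT_WEIGHT_RANGE",
    "sigma",
    "logit",
    "CircuitParams",
    "NetworkState",
    "Trajectory",
    "SimulationConfig",
    "IntegrationError",
    "integrate",
    "equilibrate",
]


def sigma(x):
    """Logistic activation 1/(1+exp(-x)), overflow-safe at both extremes."""
    x = np.asarray(x, dtype=float)
    pos = x >= 0
    ex = np.exp(np.where(pos, -x, x))
    val = np.where(pos, 1.0 / (1.0 + ex), ex / (1.0 + ex))
    return float(val) if val.ndim == 0 else val


def logit(p):
    """Inverse of :func:`sigma` on (0, 1)."""
    p = np.asarray(p, dtype=float)
    val = np.log(p) - np.log1p(-p)
    return float(val) if val.ndim == 0 else val


class IntegrationError(RuntimeError):
    """Raised when integration produces a non-finite state."""

    def __init__(self, neuron: str, step: int, time: float):
        self.neuron = neuron
        self.step = step
        self.time = time
        super().__init__(
            f"non-finite state for neuron {neuron} at step {step} (t={time:.6g} s)"
        )


@dataclass(frozen=True)
class CircuitParams:
    """The 15 free parameters of the three-neuron network.

    ``weights`` maps (source, target) label pairs to synaptic weights.
    Time constants must lie in ``TAU_RANGE`` and biases in ``BIAS_RANGE``;
    weight bounds are a search-range convention, not a hard validity limit,
    so only finiteness is enforced here.
    """

    time_constants: Mapping[str, float]
    biases: Mapping[str, float]
    weights: Mapping[tuple[str, str], float]

    def __post_init__(self):
        for n in NEURONS:
            tau = self.time_constants[n]
            if not (TAU_RANGE[0] <= tau <= TAU_RANGE[1]):
                raise ValueError(f"tau_{n}={tau} outside {TAU_RANGE}")
            th = self.biases[n]
            if not (BIAS_RANGE[0] <= th <= BIAS_RANGE[1]):
                raise ValueError(f"theta_{n}={th} outside {BIAS_RANGE}")
        for s in NEURONS:
            for t in NEURONS:
                wst = self.weights[(s, t)]
                if not np.isfinite(wst):
                    raise ValueError(f"weight {s}->{t} is not finite")
        object.__setattr__(self, "time_constants", dict(self.time_constants))
        object.__setattr__(self, "biases", dict(self.biases))
        object.__setattr__(self, "weights", dict(self.weights))

    # --- array views (fixed neuron order LP, PY, PD) ---
    def tau_array(self) -> np.ndarray:
        return np.array([self.time_constants[n] for n in NEURONS])

    def theta_array(self) -> np.ndarray:
        return np.array([self.biases[n] for n in NEURONS])

    def weight_matrix(self) -> np.ndarray:
        """W[target, source] so that dy = (-y + W @ sigma(y+theta)) / tau."""
        w = np.empty((3, 3))
        for s in NEURONS:
            for t in NEURONS:
                w[N_IDX[t], N_IDX[s]] = self.weights[(s, t)]
        return w

    def with_biases(self, **biases: float) -> "CircuitParams":
        """Copy with some biases replaced (labels as keyword names)."""
        new = dict(self.biases)
        for k, v in biases.items():
            if k not in N_IDX:
                raise KeyError(f"unknown neuron label {k!r}")
            new[k] = float(v)
        return replace(self, biases=new)

    @classmethod
    def from_arrays(cls, tau, theta, w) -> "CircuitParams":
        """Inverse of the array views; ``w`` indexed [target, source]."""
        tau = np.asarray(tau, float)
        theta = np.asarray(theta, float)
        w = np.asarray(w, float)
        return cls(
            time_constants={n: float(tau[i]) for i, n in enumerate(NEURONS)},
            biases={n: float(theta[i]) for i, n in enumerate(NEURONS)},
            weights={
                (s, t): float(w[N_IDX[t], N_IDX[s]]) for s in NEURONS for t in NEURONS
            },
        )


@dataclass(frozen=True)
class NetworkState:
    states: Mapping[str, float]
    time: float = 0.0

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("time must be >= 0")
        for n in NEURONS:
            if not np.isfinite(self.states[n]):
                raise ValueError(f"state y_{n} is not finite")
        object.__setattr__(self, "states", dict(self.states))

    def y_array(self) -> np.ndarray:
        return np.array([self.states[n] for n in NEURONS])

    @classmethod
    def zero(cls) -> "NetworkState":
        return cls(states={n: 0.0 for n in NEURONS})

    @classmethod
    def from_array(cls, y, time: float = 0.0) -> "NetworkState":
        return cls(states={n: float(y[i]) for i, n in enumerate(NEURONS)}, time=time)


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled post-transient record of states and outputs."""

    times: np.ndarray
    states: np.ndarray  # (n_samples, 3)
    outputs: np.ndarray  # (n_samples, 3)
    dt: float

    def __post_init__(self):
        if len(self.times) != len(self.states):
            raise ValueError("times/states length mismatch")

    def output(self, neuron: str) -> np.ndarray:
        return self.outputs[:, N_IDX[neuron]]

    def state(self, neuron: str) -> np.ndarray:
        return self.states[:, N_IDX[neuron]]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.01
    transient: float = 50.0
    record_duration: float = 50.0
    burst_threshold: float = 0.5
    integrator: str = "rk4"  # or "euler"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0.0 < self.burst_threshold < 1.0):
            raise ValueError("burst_threshold must lie in (0, 1)")
        if self.integrator not in ("rk4", "euler"):
            raise ValueError(f"unknown integrator {self.integrator!r}")

    def validate_for(self, params: CircuitParams) -> None:
        min_tau = min(params.time_constants[n] for n in NEURONS)
        if self.dt > min_tau / 10.0 + 1e-12:
            raise ValueError(
                f"dt={self.dt} too coarse for min tau {min_tau} (need dt <= tau/10)"
            )


def _run_kernel(params, y0, config, n_transient, n_record):
    states = rk4_record(
        np.asarray(y0, float),
        params.tau_array(),
        params.theta_array(),
        params.weight_matrix(),
        config.dt,
        n_transient,
        n_record,
        config.integrator == "euler",
    )
    if not np.all(np.isfinite(states)):
        bad = np.argwhere(~np.isfinite(states))[0]
        raise IntegrationError(
            NEURONS[int(bad[1])], n_transient + int(bad[0]), (n_transient + int(bad[0])) * config.dt
        )
    return states


def integrate(
    params: CircuitParams,
    initial: NetworkState | None = None,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Integrate with all parameters frozen and return the post-transient record."""
    config = config or SimulationConfig()
    config.validate_for(params)
    y0 = (initial or NetworkState.zero()).y_array()
    n_transient = int(round(config.transient / config.dt))
    n_record = int(round(config.record_duration / config.dt)) + 1
    states = _run_kernel(params, y0, config, n_transient, n_record)
    times = config.transient + config.dt * np.arange(n_record)
    outputs = sigma(states + params.theta_array()[None, :])
    return Trajectory(times=times, states=states, outputs=outputs, dt=config.dt)


def equilibrate(
    params: CircuitParams,
    initial: NetworkState | None = None,
    config: SimulationConfig | None = None,
    fp_tol: float = 1e-6,
) -> tuple[NetworkState, str]:
    """Run the transient and classify the limit set reached.

    Returns the settled state together with ``"fixed_point"``,
    ``"oscillatory"`` or ``"unclassified"``.  Fixed points are detected by
    state drift below ``fp_tol`` over the test window; oscillations by
    recurrent, consistently spaced level crossings of the state variables.
    """
    from .rhythm import _state_period  # deferred: rhythm imports ctrnn

    config = config or SimulationConfig()
    traj = integrate(params, initial, config)
    y_end = traj.states[-1]
    drift = np.max(np.abs(traj.states - y_end[None, :]))
    settled = NetworkState.from_array(y_end, time=float(traj.times[-1]))
    if drift < fp_tol:
        return settled, "fixed_point"
    if _state_period(traj) is not None:
        return settled, "oscillatory"
    return settled, "unclassified"
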