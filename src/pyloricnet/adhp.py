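"""Slow homeostatic regulation of neuronal biases coupled to the fast network.

Each regulated bias theta_i becomes a state variable with

    tau_theta_i  d theta_i / dt = rho(<o_i>_{s_i})

where ``<o_i>_{s_i}`` is the sliding-window average of the neuron's own
output, ``rho`` is a piecewise-linear dead-zone controller around the target
range [LB, UB], and biases are hard-clipped to [-16, 16].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._kernels import adhp_record
from .ctrnn import (
    BIAS_RANGE,
    NEURONS,
    N_IDX,
    CircuitParams,
    IntegrationError,
    NetworkState,
    SimulationConfig,
)

MIN_TIMESCALE_RATIO = 50.0

__all__ = [
    "MIN_TIMESCALE_RATIO",
    "rho",
    "ADHPMechanism",
    "AdhpRun",
    "OutcomeRecord",
    "simulate_with_adhp",
    "classify_outcome",
    "endpoint_balance",
]


def rho(x, lb: float, ub: float):
    """Dead-zone regulation drive: (LB - x) below, 0 inside, (UB - x) above.

    Continuous everywhere; for a zero-width range LB = UB = B it reduces to
    B - x.
    """
    x = np.asarray(x, dtype=float)
    val = np.where(x < lb, lb - x, np.where(x > ub, ub - x, 0.0))
    return float(val) if val.ndim == 0 else val


@dataclass(frozen=True)
class ADHPMechanism:
    """Per-neuron regulation meta-parameters for a set of regulated biases."""

    regulated: tuple[str, ...]
    lb: Mapping[str, float]
    delta: Mapping[str, float]
    window: Mapping[str, float]
    tau_theta: Mapping[str, float]

    def __post_init__(self):
        if not self.regulated or any(n not in N_IDX for n in self.regulated):
            raise ValueError(f"regulated set must be a nonempty subset of {NEURONS}")
        for n in self.regulated:
            if not (0.0 <= self.lb[n] <= 1.0):
                raise ValueError(f"LB_{n} must lie in [0, 1]")
            if self.delta[n] < 0.0:
                raise ValueError(f"range width for {n} must be >= 0")
            if not (0.0 <= self.window[n] <= 10.0):
                raise ValueError(f"window s_{n} must lie in [0, 10] seconds")
            if self.tau_theta[n] <= 0.0:
                raise ValueError(f"tau_theta_{n} must be > 0")
        object.__setattr__(self, "regulated", tuple(self.regulated))
        for f in ("lb", "delta", "window", "tau_theta"):
            object.__setattr__(self, f, {n: float(getattr(self, f)[n]) for n in self.regulated})

    def ub(self, neuron: str) -> float:
        return min(self.lb[neuron] + self.delta[neuron], 1.0)

    @property
    def is_zero_range(self) -> bool:
        return all(self.delta[n] == 0.0 for n in self.regulated)

    @classmethod
    def zero_range(
        cls,
        targets: Mapping[str, float],
        tau_theta: float = 150.0,
        window: float = 0.0,
    ) -> "ADHPMechanism":
        """Mechanism with a single target value B per regulated neuron."""
        reg = tuple(targets)
        return cls(
            regulated=reg,
            lb=dict(targets),
            delta={n: 0.0 for n in reg},
            window={n: window for n in reg},
            tau_theta={n: tau_theta for n in reg},
        )

    def scaled_tau(self, factor: float) -> "ADHPMechanism":
        return ADHPMechanism(
            regulated=self.regulated,
            lb=self.lb,
            delta=self.delta,
            window=self.window,
            tau_theta={n: self.tau_theta[n] * factor for n in self.regulated},
        )

    def check_timescale(self, params: CircuitParams) -> None:
        max_tau = max(params.time_constants[n] for n in NEURONS)
        for n in self.regulated:
            if self.tau_theta[n] < MIN_TIMESCALE_RATIO * max_tau - 1e-9:
                raise ValueError(
                    f"tau_theta_{n}={self.tau_theta[n]} violates the "
                    f"{MIN_TIMESCALE_RATIO:g}x timescale separation for max tau {max_tau}"
                )

    def _kernel_arrays(self, dt: float):
        reg = np.array([N_IDX[n] for n in self.regulated], dtype=np.int64)
        lb = np.array([self.lb[n] for n in self.regulated])
        ub = np.array([self.ub(n) for n in self.regulated])
        inv_tt = np.array([1.0 / self.tau_theta[n] for n in self.regulated])
        win = np.array(
            [max(int(round(self.window[n] / dt)), 0) for n in self.regulated],
            dtype=np.int64,
        )
        return reg, lb, ub, inv_tt, win


@dataclass(frozen=True)
class OutcomeRecord:
    classification: str  # interior_endpoint | boundary_endpoint | parametric_limit_cycle | non_convergent
    terminal_biases: dict[str, float]
    bias_bbox: dict[str, tuple[float, float]]
    pyloric_end: bool
    cycle_period: float | None = None
    pyloric_along_cycle: tuple[bool, ...] | None = None
    settled_at: float | None = None


@dataclass(frozen=True)
class AdhpRun:
    """Recorded slow trajectory of a regulation run."""

    times: np.ndarray
    biases: np.ndarray  # (n_rec, n_regulated)
    outputs: np.ndarray  # (n_rec, 3)
    regulated: tuple[str, ...]
    final_state: NetworkState
    final_params: CircuitParams
    checkpoint_params: tuple[CircuitParams, ...]
    settled_at: float | None
    outcome: OutcomeRecord | None = field(default=None, compare=False)

    def bias(self, neuron: str) -> np.ndarray:
        return self.biases[:, self.regulated.index(neuron)]


def _frozen_at(base: CircuitParams, regulated, theta_row) -> CircuitParams:
    return base.with_biases(**{n: float(v) for n, v in zip(regulated, theta_row)})


def simulate_with_adhp(
    circuit: CircuitParams,
    mechanism: ADHPMechanism,
    perturbed_biases: Mapping[str, float] | None = None,
    duration: float = 50_000.0,
    config: SimulationConfig | None = None,
    equilibration: float = 250.0,
    initial: NetworkState | None = None,
    record_every: float = 1.0,
    checkpoints: tuple[float, ...] = (),
    settle_tol: float = 0.0,
    settle_window: float = 2000.0,
    classify: bool = True,
) -> AdhpRun:
    """Equilibrate, then co-integrate the network with regulation active.

    ``perturbed_biases`` sets the listed biases before equilibration (the
    perturbation protocol); regulation starts at t = 0 after ``equilibration``
    seconds of frozen dynamics.  With ``settle_tol > 0`` the run stops early
    once all regulated biases stay within that tolerance over a trailing
    ``settle_window``; the recorded trajectory then ends at the exit time.
    """
    config = config or SimulationConfig()
    config.validate_for(circuit)
    mechanism.check_timescale(circuit)
    start = circuit if perturbed_biases is None else circuit.with_biases(**perturbed_biases)
    for n in NEURONS:
        th = start.biases[n]
        if not (BIAS_RANGE[0] <= th <= BIAS_RANGE[1]):
            raise ValueError(f"perturbed bias theta_{n}={th} outside {BIAS_RANGE}")

    dt = config.dt
    reg, lb, ub, inv_tt, win = mechanism._kernel_arrays(dt)
    y0 = (initial or NetworkState.zero()).y_array()
    theta0 = start.theta_array()

    # frozen equilibration leg
    if equilibration > 0:
        from ._kernels import rk4_record

        states = rk4_record(
            y0, start.tau_array(), theta0, start.weight_matrix(), dt,
            int(round(equilibration / dt)), 1, False,
        )
        y0 = states[-1].copy()
        if not np.all(np.isfinite(y0)):
            raise IntegrationError("?", int(round(equilibration / dt)), equilibration)

    rec_every = max(int(round(record_every / dt)), 1)
    n_steps = int(round(duration / dt))
    t_rec, th_rec, o_rec, n_rec, y_end, theta_end, settled = adhp_record(
        y0, start.tau_array(), theta0, start.weight_matrix(), dt, n_steps,
        reg, lb, ub, inv_tt, win,
        BIAS_RANGE[0], BIAS_RANGE[1],
        rec_every,
        max(int(round(settle_window / record_every)), 2),
        settle_tol,
        max(int(round(settle_window / record_every)) // 4, 1),
    )
    if not np.all(np.isfinite(y_end)):
        raise IntegrationError("?", n_steps, duration)
    times = t_rec[:n_rec].copy()
    biases = th_rec[:n_rec].copy()
    outputs = o_rec[:n_rec].copy()
    settled_at = float(settled) if settled >= 0 else None

    final_params = _frozen_at(circuit, mechanism.regulated, theta_end[reg])
    chk_params = []
    for t_chk in checkpoints:
        if settled_at is not None and t_chk > times[-1]:
            row = biases[-1]
        else:
            idx = int(np.argmin(np.abs(times - t_chk)))
            row = biases[idx]
        chk_params.append(_frozen_at(circuit, mechanism.regulated, row))

    run = AdhpRun(
        times=times,
        biases=biases,
        outputs=outputs,
        regulated=mechanism.regulated,
        final_state=NetworkState.from_array(y_end, time=float(times[-1])),
        final_params=final_params,
        checkpoint_params=tuple(chk_params),
        settled_at=settled_at,
    )
    if classify:
        outcome = classify_outcome(run, circuit, config)
        object.__setattr__(run, "outcome", outcome)
    return run


def _recurrence_period(t: np.ndarray, x: np.ndarray, rel_tol: float = 0.1):
    level = 0.5 * (np.min(x) + np.max(x))
    above = x > level
    ups = np.nonzero(~above[:-1] & above[1:])[0]
    if len(ups) < 3:
        return None
    iv = np.diff(t[ups])
    med = float(np.median(iv))
    if med <= 0 or np.max(np.abs(iv - med)) > rel_tol * med:
        return None
    return float(np.mean(iv))


def classify_outcome(
    run: AdhpRun,
    circuit: CircuitParams,
    config: SimulationConfig | None = None,
    endpoint_tol: float = 0.05,
    cycle_tol: float = 0.5,
    boundary_tol: float = 1e-3,
    window: float = 2000.0,
) -> OutcomeRecord:
    """Classify the terminal behaviour of the slow bias trajectory.

    Endpoints require the trailing-window excursion of every regulated bias
    to stay below ``endpoint_tol`` (boundary endpoints when pinned at the
    bias limits); excursions above ``cycle_tol`` with a consistent recurrence
    are parametric limit cycles; anything else is non-convergent.
    """
    from .fitness import evaluate_circuit  # deferred import cycle

    config = config or SimulationConfig()
    t = run.times
    window = min(window, 0.5 * (t[-1] - t[0]))  # short runs: use the last half
    tail = t >= t[-1] - window
    th_tail = run.biases[tail]
    excursion = th_tail.max(axis=0) - th_tail.min(axis=0)
    terminal = {n: float(run.biases[-1, j]) for j, n in enumerate(run.regulated)}
    bbox = {
        n: (float(th_tail[:, j].min()), float(th_tail[:, j].max()))
        for j, n in enumerate(run.regulated)
    }
    pyloric_end = evaluate_circuit(run.final_params, config).pyloric

    if run.settled_at is not None or np.all(excursion < endpoint_tol):
        pinned = any(
            abs(abs(v) - BIAS_RANGE[1]) < boundary_tol for v in terminal.values()
        )
        cls = "boundary_endpoint" if pinned else "interior_endpoint"
        return OutcomeRecord(
            classification=cls,
            terminal_biases=terminal,
            bias_bbox=bbox,
            pyloric_end=pyloric_end,
            settled_at=run.settled_at,
        )

    if np.any(excursion > cycle_tol):
        j = int(np.argmax(excursion))
        period = _recurrence_period(t[tail], th_tail[:, j])
        if period is not None:
            phases = np.linspace(t[-1] - period, t[-1], 8, endpoint=False)
            along = tuple(
                evaluate_circuit(
                    _frozen_at(
                        circuit,
                        run.regulated,
                        run.biases[int(np.argmin(np.abs(t - ph)))],
                    ),
                    config,
                ).pyloric
                for ph in phases
            )
            return OutcomeRecord(
                classification="parametric_limit_cycle",
                terminal_biases=terminal,
                bias_bbox=bbox,
                pyloric_end=pyloric_end,
                cycle_period=period,
                pyloric_along_cycle=along,
            )

    return OutcomeRecord(
        classification="non_convergent",
        terminal_biases=terminal,
        bias_bbox=bbox,
        pyloric_end=pyloric_end,
    )


def endpoint_balance(
    circuit: CircuitParams,
    mechanism: ADHPMechanism,
    run: AdhpRun,
    config: SimulationConfig | None = None,
    n_cycles: int = 30,
    lead: float = 2000.0,
) -> dict[str, dict[str, float]] | None:
    """Per-cycle regulation balance at a converged endpoint.

    Continues the run from its terminal state and measures, for each
    regulated neuron, the per-cycle integral of rho (recovered exactly as
    tau_theta times the bias drift per rhythm cycle) and the gap between the
    cycle-averaged output of the frozen terminal circuit and the target
    midpoint.  Returns None when the terminal circuit has no detectable
    rhythm period.
    """
    from .fitness import evaluate_circuit

    config = config or SimulationConfig()
    fb = evaluate_circuit(run.final_params, config)
    desc = fb.descriptor
    if desc is None or desc.period is None:
        return None
    T = desc.period
    dt = config.dt
    # lead-in lets residual slow-transient drift decay before measuring
    lead = max(mechanism.window.values()) + max(2.0 * T, lead)
    measure = n_cycles * T
    reg, lb, ub, inv_tt, win = mechanism._kernel_arrays(dt)
    t_rec, th_rec, o_rec, n_rec, y_end, theta_end, _ = adhp_record(
        run.final_state.y_array(),
        circuit.tau_array(),
        run.final_params.theta_array(),
        circuit.weight_matrix(),
        dt,
        int(round((lead + measure) / dt)),
        reg, lb, ub, inv_tt, win,
        BIAS_RANGE[0], BIAS_RANGE[1],
        1, 2, 0.0, 1,
    )
    i0 = int(round(lead / dt))
    # sample theta at equal rhythm phases: use upward threshold crossings of a
    # bursting neuron in the regulated run itself, so the within-cycle
    # parametric micro-oscillation cancels exactly
    theta_first = theta_last = k_cycles = None
    for col in range(3):
        o = o_rec[i0:n_rec, col]
        above = o > config.burst_threshold
        ups = np.nonzero(~above[:-1] & above[1:])[0]
        if len(ups) >= 2:
            k_cycles = len(ups) - 1
            # interpolate theta at the exact crossing instants so both ends
            # sample the same phase of the parametric micro-oscillation
            def theta_at_crossing(m):
                m_abs = int(m) + i0
                frac = (config.burst_threshold - o_rec[m_abs, col]) / (
                    o_rec[m_abs + 1, col] - o_rec[m_abs, col]
                )
                return th_rec[m_abs] + frac * (th_rec[m_abs + 1] - th_rec[m_abs])

            theta_first = theta_at_crossing(ups[0])
            theta_last = theta_at_crossing(ups[-1])
            break
    if theta_first is None:
        theta_first, theta_last = th_rec[i0], th_rec[n_rec - 1]
        k_cycles = max(int(round((n_rec - 1 - i0) * dt / T)), 1)
    result = {}
    for j, n in enumerate(mechanism.regulated):
        drift = float(theta_last[j] - theta_first[j])
        per_cycle = mechanism.tau_theta[n] * drift / k_cycles
        target_mid = 0.5 * (mechanism.lb[n] + mechanism.ub(n))
        result[n] = {
            "per_cycle_integral": per_cycle,
            "mean_output": desc.averages[n],
            "target_gap": desc.averages[n] - target_mid,
        }
    return result


def batch_recover(
    circuit: CircuitParams,
    mechanism: ADHPMechanism,
    perturbations,
    duration: float = 50_000.0,
    config: SimulationConfig | None = None,
    equilibration: float = 250.0,
    settle_tol: float = 0.02,
    settle_window: float = 2000.0,
) -> list[CircuitParams]:
    """Run many perturbation legs at once; return the frozen terminal circuits.

    A fast path for recovery sweeps: no trajectories are recorded and legs
    are frozen individually once their biases settle.  Requires
    instantaneous activity detection (all windows 0); falls back to
    :func:`simulate_with_adhp` legs otherwise.
    """
    from ._kernels import adhp_batch_final

    config = config or SimulationConfig()
    config.validate_for(circuit)
    mechanism.check_timescale(circuit)
    perturbations = list(perturbations)
    if any(mechanism.window[n] > 0 for n in mechanism.regulated):
        out = []
        for pert in perturbations:
            run = simulate_with_adhp(
                circuit, mechanism, perturbed_biases=pert, duration=duration,
                config=config, equilibration=equilibration,
                settle_tol=settle_tol, settle_window=settle_window,
                classify=False,
            )
            out.append(run.final_params)
        return out

    dt = config.dt
    reg, lb, ub, inv_tt, _ = mechanism._kernel_arrays(dt)
    B = len(perturbations)
    y0 = np.zeros((B, 3))
    theta0 = np.empty((B, 3))
    for b, pert in enumerate(perturbations):
        theta0[b] = circuit.with_biases(**pert).theta_array()
    check_every = max(int(round(settle_window / (8.0 * dt))) , 1)
    theta_f, y_f, _ = adhp_batch_final(
        y0, circuit.tau_array(), theta0, circuit.weight_matrix(), dt,
        int(round(equilibration / dt)), int(round(duration / dt)),
        reg, lb, ub, inv_tt,
        BIAS_RANGE[0], BIAS_RANGE[1],
        check_every, 8, settle_tol,
    )
    if not np.all(np.isfinite(theta_f)):
        raise IntegrationError("?", int(round(duration / dt)), duration)
    return [
        _frozen_at(circuit, mechanism.regulated, theta_f[b][reg]) for b in range(B)
    ]
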