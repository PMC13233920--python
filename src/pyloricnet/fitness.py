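"""Staged pyloricness fitness, timing bonus, and regulator fitness.

Base fitness accrues 0.05 per bursting neuron plus, once all three neurons
burst, 0.05 per satisfied ordering criterion; 0.3 marks a pyloric circuit.
The timing bonus inverts the summed absolute z-scores of the five timing
metrics against reference statistics.  Regulator fitness averages pyloric
fitness (plus a flat recovery bonus) over a grid of bias perturbations and
two measurement checkpoints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .ctrnn import (
    CircuitParams,
    NetworkState,
    SimulationConfig,
    IntegrationError,
    integrate,
)
from .rhythm import CriteriaFlags, RhythmDescriptor, analyze

PYLORIC_BASE_FITNESS = 0.3
TIMING_EPS = 1e-6

#: Duty-cycle means for the LP/PY/PD triphasic rhythm (fractions of the cycle
#: spent bursting).  Standard deviations and phase statistics have no
#: published defaults here and must be supplied by the caller.
REFERENCE_DUTY_MEANS = {"LP": 0.264, "PY": 0.348, "PD": 0.385}

__all__ = [
    "PYLORIC_BASE_FITNESS",
    "TIMING_EPS",
    "REFERENCE_DUTY_MEANS",
    "TimingStats",
    "FitnessBreakdown",
    "AdhpEvalProtocol",
    "base_fitness",
    "timing_fitness",
    "total_fitness",
    "evaluate_circuit",
    "adhp_fitness",
]


@dataclass(frozen=True)
class TimingStats:
    """Reference duty-cycle and phase statistics used for the timing bonus."""

    duty_mean: dict[str, float]
    duty_sd: dict[str, float]
    phase_mean: dict[str, float]  # keys LP, PY (phases relative to PD onset)
    phase_sd: dict[str, float]

    def __post_init__(self):
        for n in ("LP", "PY", "PD"):
            if not (0.0 < self.duty_mean[n] < 1.0):
                raise ValueError(f"duty mean for {n} must lie in (0,1)")
            if self.duty_sd[n] <= 0:
                raise ValueError(f"duty SD for {n} must be > 0")
        for n in ("LP", "PY"):
            if not (0.0 < self.phase_mean[n] < 1.0):
                raise ValueError(f"phase mean for {n} must lie in (0,1)")
            if self.phase_sd[n] <= 0:
                raise ValueError(f"phase SD for {n} must be > 0")


@dataclass(frozen=True)
class FitnessBreakdown:
    n_bursting: int
    criteria: CriteriaFlags
    base: float
    timing: float | None
    total: float
    at_mean: bool = False
    descriptor: RhythmDescriptor | None = field(default=None, repr=False)

    @property
    def pyloric(self) -> bool:
        return self.base == PYLORIC_BASE_FITNESS


def base_fitness(n_bursting: int, criteria: CriteriaFlags) -> float:
    """0.05 * (n + [n=3] * (c_gap + c_PYS<LPE + c_LPE<PYE))."""
    if n_bursting not in (0, 1, 2, 3):
        raise ValueError("n_bursting must be in 0..3")
    bonus = criteria.count() if n_bursting == 3 else 0
    # snap to the exact 0.05 grid so P_b == 0.3 is a reliable pyloric test
    return round(0.05 * (n_bursting + bonus), 2)


def timing_fitness(
    duty: dict[str, float],
    phase: dict[str, float],
    stats: TimingStats,
    eps: float = TIMING_EPS,
) -> tuple[float, bool]:
    """Timing bonus 5 / sum(|z|) over three duty cycles and two phases.

    The denominator is floored at ``eps`` to keep perfect timing finite;
    returns (value, at_mean_flag).
    """
    if duty is None or phase is None:
        raise ValueError("timing metrics undefined; timing fitness requires a parseable rhythm")
    z_sum = sum(
        abs((duty[n] - stats.duty_mean[n]) / stats.duty_sd[n]) for n in ("LP", "PY", "PD")
    ) + sum(
        abs((phase[n] - stats.phase_mean[n]) / stats.phase_sd[n]) for n in ("LP", "PY")
    )
    at_mean = z_sum < eps
    return 5.0 / max(z_sum, eps), at_mean


def total_fitness(base: float, timing: float | None) -> float:
    """P = P_b + [P_b = 0.3] * P_t."""
    if base == PYLORIC_BASE_FITNESS and timing is not None:
        return base + timing
    return base


def evaluate_circuit(
    params: CircuitParams,
    config: SimulationConfig | None = None,
    timing_stats: TimingStats | None = None,
    initial: NetworkState | None = None,
) -> FitnessBreakdown:
    """Simulate, parse the rhythm, and assemble the full fitness breakdown."""
    config = config or SimulationConfig()
    traj = integrate(params, initial, config)
    desc = analyze(traj, config.burst_threshold)
    base = base_fitness(desc.n_bursting, desc.criteria)
    timing = None
    at_mean = False
    if (
        base == PYLORIC_BASE_FITNESS
        and timing_stats is not None
        and desc.duty is not None
        and desc.phase is not None
    ):
        timing, at_mean = timing_fitness(desc.duty, desc.phase, timing_stats)
    return FitnessBreakdown(
        n_bursting=desc.n_bursting,
        criteria=desc.criteria,
        base=base,
        timing=timing,
        total=total_fitness(base, timing),
        at_mean=at_mean,
        descriptor=desc,
    )


@dataclass(frozen=True)
class AdhpEvalProtocol:
    """Evaluation protocol for a regulator on a circuit.

    Biases on the regulated axes are set to each point of the perturbation
    grid (the cartesian product of ``grid_values`` over the regulated axes),
    the network equilibrates for ``equilibration`` seconds, then regulation
    runs with pyloric fitness measured at each checkpoint; ``alpha`` is the
    flat bonus per pyloric measurement.
    """

    grid_values: tuple[float, ...] = (-9.0, 0.0, 9.0)
    equilibration: float = 250.0
    checkpoints: tuple[float, ...] = (2500.0, 5000.0)
    alpha: float = 25.0
    timing_stats: TimingStats | None = None

    def grid(self, n_axes: int):
        return list(itertools.product(self.grid_values, repeat=n_axes))


def adhp_fitness(
    circuit: CircuitParams,
    mechanism,
    protocol: AdhpEvalProtocol | None = None,
    config: SimulationConfig | None = None,
) -> tuple[float, list[dict]]:
    """Average [P + [pyloric]*alpha] over all perturbations and checkpoints.

    A perturbation leg that fails to integrate scores 0 for its measurements
    and is recorded in the returned log.
    """
    from .adhp import simulate_with_adhp  # deferred: adhp imports fitness helpers

    protocol = protocol or AdhpEvalProtocol()
    config = config or SimulationConfig()
    axes = mechanism.regulated
    scores = []
    log = []
    for point in protocol.grid(len(axes)):
        perturbed = dict(zip(axes, point))
        entry = {"perturbation": perturbed, "measurements": []}
        try:
            run = simulate_with_adhp(
                circuit,
                mechanism,
                perturbed_biases=perturbed,
                duration=max(protocol.checkpoints),
                config=config,
                equilibration=protocol.equilibration,
                checkpoints=protocol.checkpoints,
            )
            for t_chk, frozen in zip(protocol.checkpoints, run.checkpoint_params):
                fb = evaluate_circuit(frozen, config, protocol.timing_stats)
                score = fb.total + (protocol.alpha if fb.pyloric else 0.0)
                scores.append(score)
                entry["measurements"].append(
                    {"t": t_chk, "P": fb.total, "pyloric": fb.pyloric, "score": score}
                )
        except IntegrationError as err:
            n_missing = len(protocol.checkpoints) - len(entry["measurements"])
            scores.extend([0.0] * n_missing)
            entry["error"] = str(err)
        log.append(entry)
    return sum(scores) / len(scores), log
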