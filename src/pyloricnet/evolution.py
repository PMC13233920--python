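"""Microbial genetic algorithm for circuits and regulators.

Genomes are vectors in [0, 1] mapped affinely onto parameter ranges.  The
engine is a steady-state tournament-of-two: pick two distinct individuals,
overwrite the loser with a mutated copy of the winner (Gaussian mutation in
genome space, reflected at the unit bounds).  One generation is
population-size tournaments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .adhp import ADHPMechanism
from .ctrnn import (
    BIAS_RANGE,
    DEFAULT_WEIGHT_RANGE,
    NEURONS,
    TAU_RANGE,
    CircuitParams,
    SimulationConfig,
)
from .fitness import (
    PYLORIC_BASE_FITNESS,
    AdhpEvalProtocol,
    TimingStats,
    adhp_fitness,
    evaluate_circuit,
)

LB_RANGE = (0.0, 1.0)
DELTA_RANGE = (0.0, 1.0)
WINDOW_RANGE = (0.0, 10.0)
TAU_THETA_RANGE = (100.0, 200.0)

#: post-hoc robustness grid of bias perturbations (per regulated axis)
ROBUSTNESS_GRID = (-15.0, -9.0, -3.0, 3.0, 9.0, 15.0)

__all__ = [
    "GAConfig",
    "CircuitRun",
    "MechanismRun",
    "decode_circuit",
    "encode_circuit",
    "decode_mechanism",
    "encode_mechanism",
    "run_microbial",
    "evolve_circuits",
    "evolve_adhp",
    "robustness_label",
    "metaparameter_census",
]


@dataclass(frozen=True)
class GAConfig:
    population: int = 100
    generations: int = 100
    mutation_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")


def _affine(gene, lo, hi):
    return lo + gene * (hi - lo)


def _inverse(value, lo, hi):
    return (value - lo) / (hi - lo)


def decode_circuit(
    genome: np.ndarray, weight_range=DEFAULT_WEIGHT_RANGE, tau_range=TAU_RANGE
) -> CircuitParams:
    """15 genes: 3 time constants, 3 biases, 9 weights (source-major order).

    ``tau_range`` may restrict the search to a subrange of the allowed time
    constants (e.g. slow circuits that tolerate coarse integration steps).
    """
    g = np.asarray(genome, float)
    if g.shape != (15,):
        raise ValueError("circuit genome must have 15 genes")
    tau = {n: _affine(g[i], *tau_range) for i, n in enumerate(NEURONS)}
    theta = {n: _affine(g[3 + i], *BIAS_RANGE) for i, n in enumerate(NEURONS)}
    weights = {}
    k = 6
    for s in NEURONS:
        for t in NEURONS:
            weights[(s, t)] = _affine(g[k], *weight_range)
            k += 1
    return CircuitParams(time_constants=tau, biases=theta, weights=weights)


def encode_circuit(
    params: CircuitParams, weight_range=DEFAULT_WEIGHT_RANGE, tau_range=TAU_RANGE
) -> np.ndarray:
    g = np.empty(15)
    for i, n in enumerate(NEURONS):
        g[i] = _inverse(params.time_constants[n], *tau_range)
        g[3 + i] = _inverse(params.biases[n], *BIAS_RANGE)
    k = 6
    for s in NEURONS:
        for t in NEURONS:
            g[k] = _inverse(params.weights[(s, t)], *weight_range)
            k += 1
    return g


def decode_mechanism(genome: np.ndarray, regulated: tuple[str, ...]) -> ADHPMechanism:
    """4 genes per regulated neuron: LB, range width, window, tau_theta."""
    g = np.asarray(genome, float)
    if g.shape != (4 * len(regulated),):
        raise ValueError(f"mechanism genome must have {4 * len(regulated)} genes")
    lb, delta, window, tau_theta = {}, {}, {}, {}
    for j, n in enumerate(regulated):
        lb[n] = _affine(g[4 * j], *LB_RANGE)
        delta[n] = _affine(g[4 * j + 1], *DELTA_RANGE)
        window[n] = _affine(g[4 * j + 2], *WINDOW_RANGE)
        tau_theta[n] = _affine(g[4 * j + 3], *TAU_THETA_RANGE)
    return ADHPMechanism(
        regulated=regulated, lb=lb, delta=delta, window=window, tau_theta=tau_theta
    )


def encode_mechanism(mech: ADHPMechanism) -> np.ndarray:
    g = np.empty(4 * len(mech.regulated))
    for j, n in enumerate(mech.regulated):
        g[4 * j] = _inverse(mech.lb[n], *LB_RANGE)
        g[4 * j + 1] = _inverse(mech.delta[n], *DELTA_RANGE)
        g[4 * j + 2] = _inverse(mech.window[n], *WINDOW_RANGE)
        g[4 * j + 3] = _inverse(mech.tau_theta[n], *TAU_THETA_RANGE)
    return g


def _reflect(g: np.ndarray) -> np.ndarray:
    r = np.abs(g) % 2.0
    return np.minimum(r, 2.0 - r)


def run_microbial(eval_fn, n_genes: int, config: GAConfig):
    """Generic steady-state GA; returns (best_genome, best_fitness, history).

    ``history`` holds the best population fitness after each generation; it
    is non-decreasing because the tournament winner is never replaced.
    """
    rng = np.random.default_rng(config.seed)
    pop = rng.random((config.population, n_genes))
    fit = np.array([eval_fn(ind) for ind in pop], dtype=float)
    history = [float(fit.max())]
    for _ in range(config.generations):
        for _ in range(config.population):
            i, j = rng.choice(config.population, size=2, replace=False)
            win, lose = (i, j) if fit[i] >= fit[j] else (j, i)
            child = _reflect(pop[win] + rng.normal(0.0, config.mutation_sigma, n_genes))
            pop[lose] = child
            fit[lose] = eval_fn(child)
        history.append(float(fit.max()))
    best = int(np.argmax(fit))
    return pop[best].copy(), float(fit[best]), history


@dataclass(frozen=True)
class CircuitRun:
    params: CircuitParams
    genome: np.ndarray = field(repr=False)
    fitness: float
    base: float
    timing: float | None
    ordering: tuple[str, ...] | None
    admitted_base_db: bool
    admitted_timing_db: bool
    history: list[float] = field(repr=False)
    config: GAConfig = field(repr=False)
    mode: str = "base"


def evolve_circuits(
    config: GAConfig,
    mode: str = "base",
    timing_stats: TimingStats | None = None,
    sim_config: SimulationConfig | None = None,
    weight_range=DEFAULT_WEIGHT_RANGE,
    tau_range=TAU_RANGE,
) -> CircuitRun:
    """One evolutionary run against pyloric fitness; returns the best circuit.

    ``mode="base"`` optimizes P_b only; ``mode="timing"`` additionally awards
    the timing bonus (requires ``timing_stats``).  The run is admitted to the
    base database iff P_b = 0.3, and to the timing database iff P >= 2.
    """
    if mode not in ("base", "timing"):
        raise ValueError("mode must be 'base' or 'timing'")
    if mode == "timing" and timing_stats is None:
        raise ValueError("timing mode requires timing_stats")
    sim_config = sim_config or SimulationConfig()
    stats = timing_stats if mode == "timing" else None

    def eval_fn(genome):
        fb = evaluate_circuit(
            decode_circuit(genome, weight_range, tau_range), sim_config, stats
        )
        return fb.total if mode == "timing" else fb.base

    genome, best_fit, history = run_microbial(eval_fn, 15, config)
    params = decode_circuit(genome, weight_range, tau_range)
    fb = evaluate_circuit(params, sim_config, stats)
    return CircuitRun(
        params=params,
        genome=genome,
        fitness=best_fit,
        base=fb.base,
        timing=fb.timing,
        ordering=fb.descriptor.ordering if fb.descriptor else None,
        admitted_base_db=fb.base == PYLORIC_BASE_FITNESS,
        admitted_timing_db=fb.base == PYLORIC_BASE_FITNESS and fb.total >= 2.0,
        history=history,
        config=config,
        mode=mode,
    )


@dataclass(frozen=True)
class MechanismRun:
    mechanism: ADHPMechanism
    genome: np.ndarray = field(repr=False)
    fitness: float
    label: str  # "full" | "mixed" | "none"
    recovered: int
    tested: int
    history: list[float] = field(repr=False)
    config: GAConfig = field(repr=False)


def robustness_label(
    circuit: CircuitParams,
    mechanism: ADHPMechanism,
    sim_config: SimulationConfig | None = None,
    grid_values: tuple[float, ...] = ROBUSTNESS_GRID,
    duration: float = 5000.0,
    equilibration: float = 250.0,
    settle_tol: float = 0.0,
) -> tuple[str, int, int]:
    """Post-hoc success label over the extended perturbation grid.

    Runs regulation from every grid perturbation and checks pyloricness of
    the frozen terminal circuit; labels full / mixed / none accordingly.
    """
    from .adhp import batch_recover

    sim_config = sim_config or SimulationConfig()
    points = list(itertools.product(grid_values, repeat=len(mechanism.regulated)))
    finals = batch_recover(
        circuit,
        mechanism,
        [dict(zip(mechanism.regulated, p)) for p in points],
        duration=duration,
        config=sim_config,
        equilibration=equilibration,
        settle_tol=settle_tol,
    )
    recovered = sum(
        int(evaluate_circuit(f, sim_config).pyloric) for f in finals
    )
    if recovered == len(points):
        label = "full"
    elif recovered > 0:
        label = "mixed"
    else:
        label = "none"
    return label, recovered, len(points)


def evolve_adhp(
    circuit: CircuitParams,
    config: GAConfig,
    protocol: AdhpEvalProtocol | None = None,
    regulated: tuple[str, ...] = ("LP", "PD"),
    sim_config: SimulationConfig | None = None,
    robustness: bool = True,
) -> MechanismRun:
    """Evolve a regulator for one circuit against the ADHP fitness."""
    protocol = protocol or AdhpEvalProtocol()
    sim_config = sim_config or SimulationConfig()

    def eval_fn(genome):
        mech = decode_mechanism(genome, regulated)
        score, _ = adhp_fitness(circuit, mech, protocol, sim_config)
        return score

    genome, best_fit, history = run_microbial(eval_fn, 4 * len(regulated), config)
    mech = decode_mechanism(genome, regulated)
    if robustness:
        label, recovered, tested = robustness_label(circuit, mech, sim_config)
    else:
        label, recovered, tested = "untested", 0, 0
    return MechanismRun(
        mechanism=mech,
        genome=genome,
        fitness=best_fit,
        label=label,
        recovered=recovered,
        tested=tested,
        history=history,
        config=config,
    )


def metaparameter_census(runs) -> dict[str, dict[str, dict[str, np.ndarray]]]:
    """Meta-parameter values grouped by success label.

    Returns ``census[label][field][neuron]`` arrays for fields lb, delta,
    window, tau_theta; input order does not matter.
    """
    census: dict[str, dict[str, dict[str, list[float]]]] = {}
    for run in sorted(runs, key=lambda r: (r.label, r.fitness)):
        mech = run.mechanism
        bucket = census.setdefault(
            run.label, {f: {} for f in ("lb", "delta", "window", "tau_theta")}
        )
        for f in ("lb", "delta", "window", "tau_theta"):
            for n in mech.regulated:
                bucket[f].setdefault(n, []).append(getattr(mech, f)[n])
    return {
        label: {
            f: {n: np.asarray(v) for n, v in per.items()} for f, per in fields.items()
        }
        for label, fields in census.items()
    }
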