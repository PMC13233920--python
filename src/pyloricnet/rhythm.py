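"""Burst parsing, period detection, ordering classification and timing metrics.

A rhythm is described by six burst-boundary events per cycle
(``LP_S``, ``LP_E``, ``PY_S``, ``PY_E``, ``PD_S``, ``PD_E``), folded into a
single cycle anchored at the start of the LP burst.  A neuron whose burst
wraps the cycle boundary has its end event folded to an earlier phase than
its start; this convention makes all 5! = 120 orderings of the post-anchor
events realizable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .ctrnn import NEURONS, N_IDX, Trajectory

EVENTS = ("LP_S", "LP_E", "PY_S", "PY_E", "PD_S", "PD_E")
FEATURED_ORDERING = ("LP_S", "PY_S", "LP_E", "PY_E", "PD_S", "PD_E")

__all__ = [
    "EVENTS",
    "FEATURED_ORDERING",
    "BurstTrain",
    "CriteriaFlags",
    "RhythmDescriptor",
    "parse_bursts",
    "detect_period",
    "classify_ordering",
    "evaluate_criteria",
    "enumerate_orderings",
    "ordering_criteria",
    "timing_metrics",
    "cycle_average",
    "analyze",
]


@dataclass(frozen=True)
class CriteriaFlags:
    """The three binary pyloric ordering criteria."""

    c_gap: bool
    c_pys_before_lpe: bool
    c_lpe_before_pye: bool

    def all(self) -> bool:
        return self.c_gap and self.c_pys_before_lpe and self.c_lpe_before_pye

    def count(self) -> int:
        return int(self.c_gap) + int(self.c_pys_before_lpe) + int(self.c_lpe_before_pye)


NO_CRITERIA = CriteriaFlags(False, False, False)


@dataclass(frozen=True)
class BurstTrain:
    neuron: str
    status: str  # "bursting" | "silent" | "tonic"
    episodes: tuple[tuple[float, float], ...]
    up_crossings: np.ndarray = field(repr=False)
    down_crossings: np.ndarray = field(repr=False)

    @property
    def crosses_both_ways(self) -> bool:
        return len(self.up_crossings) > 0 and len(self.down_crossings) > 0


def _interp_crossings(t: np.ndarray, o: np.ndarray, threshold: float):
    """Sub-sample crossing times of ``threshold`` by linear interpolation.

    A sample exactly at threshold counts as *below* (strict ``>`` defines
    bursting).  Returns (up_times, down_times).
    """
    above = o > threshold
    flips = np.nonzero(above[1:] != above[:-1])[0]
    if len(flips) == 0:
        return np.empty(0), np.empty(0)
    frac = (threshold - o[flips]) / (o[flips + 1] - o[flips])
    times = t[flips] + frac * (t[flips + 1] - t[flips])
    going_up = ~above[flips]
    return times[going_up], times[~going_up]


def parse_bursts(trajectory: Trajectory, threshold: float = 0.5) -> dict[str, BurstTrain]:
    """Split each neuron's output trace into burst episodes.

    Episodes are complete (up-crossing followed by down-crossing) intervals;
    partial bursts touching the record edges contribute crossings but no
    episode.
    """
    trains = {}
    for n in NEURONS:
        o = trajectory.output(n)
        ups, downs = _interp_crossings(trajectory.times, o, threshold)
        if not np.any(o > threshold):
            status = "silent"
        elif not np.any(o <= threshold):
            status = "tonic"
        else:
            status = "bursting"
        episodes = []
        for u in ups:
            later = downs[downs > u]
            if len(later):
                d = later[0]
                nxt = ups[ups > u]
                if len(nxt) == 0 or d < nxt[0]:
                    episodes.append((float(u), float(d)))
        trains[n] = BurstTrain(
            neuron=n,
            status=status,
            episodes=tuple(episodes),
            up_crossings=ups,
            down_crossings=downs,
        )
    return trains


def _consistent_period(crossings: np.ndarray, rel_tol: float, max_intervals: int):
    if len(crossings) < 4:
        return None
    iv = np.diff(crossings[-(max_intervals + 1):])
    med = float(np.median(iv))
    if med <= 0:
        return None
    if np.max(np.abs(iv - med)) <= rel_tol * med:
        return float(np.mean(iv))
    return None


def detect_period(
    trajectory: Trajectory,
    threshold: float = 0.5,
    rel_tol: float = 0.01,
    max_intervals: int = 8,
) -> float | None:
    """Estimate the rhythm period from upward threshold crossings.

    Uses LP as the reference neuron, falling back to PY then PD; requires at
    least three consecutive inter-crossing intervals agreeing within
    ``rel_tol``.  Returns ``None`` for fixed points or inconsistent rhythms.
    """
    trains = parse_bursts(trajectory, threshold)
    for n in NEURONS:
        T = _consistent_period(trains[n].up_crossings, rel_tol, max_intervals)
        if T is not None:
            return T
    return None


def _state_period(
    trajectory: Trajectory, rel_tol: float = 0.02, amp_tol: float = 1e-4
) -> float | None:
    """Period of any oscillation (including sub-threshold), from mid-level
    crossings of the state variables."""
    for n in NEURONS:
        y = trajectory.state(n)
        lo, hi = float(np.min(y)), float(np.max(y))
        if hi - lo < amp_tol:
            continue
        ups, _ = _interp_crossings(trajectory.times, y, 0.5 * (lo + hi))
        T = _consistent_period(ups, rel_tol, 8)
        if T is not None:
            return T
    return None


def _fold_events(trains, period, t_end, tie_tol):
    """Fold one LP_S-anchored cycle of events.

    The cycle runs between two consecutive LP up-crossings (the local period,
    which may deviate slightly from the averaged ``period`` estimate; they
    must agree within 5%).  Returns (events dict name->folded time, anchor
    time, tie flag) or None if any neuron lacks exactly one burst per cycle
    or no anchor fits with a wrap margin inside the record.
    """
    lp_ups = trains["LP"].up_crossings
    if len(lp_ups) < 2:
        return None
    anchor = local_T = None
    for i in range(len(lp_ups) - 2, -1, -1):
        cand_T = float(lp_ups[i + 1] - lp_ups[i])
        if lp_ups[i + 1] + cand_T <= t_end + 1e-9:
            anchor, local_T = float(lp_ups[i]), cand_T
            break
    if anchor is None:
        anchor, local_T = float(lp_ups[0]), float(lp_ups[1] - lp_ups[0])
    if not (0.95 * period <= local_T <= 1.05 * period):
        return None
    events = {"LP_S": 0.0}
    for n in NEURONS:
        ups = trains[n].up_crossings
        in_cycle = ups[(ups >= anchor - 1e-12) & (ups < anchor + local_T - 1e-12)]
        if len(in_cycle) != 1:
            return None
        start = float(in_cycle[0])
        downs = trains[n].down_crossings
        later = downs[downs > start + 1e-12]
        if len(later) == 0:
            return None
        end = float(later[0])
        if end - start >= local_T:
            return None  # burst longer than the cycle: not one clean burst
        if n != "LP":
            events[f"{n}_S"] = (start - anchor) % local_T
        events[f"{n}_E"] = (end - anchor) % local_T
    folded = sorted(events.values())
    tie = any(b - a < tie_tol for a, b in zip(folded, folded[1:]))
    return events, anchor, local_T, tie


def classify_ordering(
    bursts: dict[str, BurstTrain],
    period: float,
    t_end: float | None = None,
    tie_tol: float = 0.0,
) -> tuple[str, ...] | None:
    """Return the LP_S-anchored event sequence (one of 120), or ``None``.

    ``None`` when a neuron has other than one burst per cycle, or when two
    events coincide within ``tie_tol``.
    """
    if t_end is None:
        t_end = max(
            (tr.down_crossings[-1] for tr in bursts.values() if len(tr.down_crossings)),
            default=0.0,
        )
    res = _fold_events(bursts, period, t_end, tie_tol)
    if res is None:
        return None
    events, _, _, tie = res
    if tie:
        return None
    return tuple(sorted(events, key=events.get))


def ordering_criteria(ordering: tuple[str, ...]) -> CriteriaFlags:
    """Criteria flags implied by an abstract event ordering.

    In the folded cycle a neuron is mid-burst at the anchor instant exactly
    when its end event precedes its start event, so the silence-gap criterion
    holds iff both PY and PD start before they end.
    """
    pos = {e: i for i, e in enumerate(ordering)}
    return CriteriaFlags(
        c_gap=pos["PY_S"] < pos["PY_E"] and pos["PD_S"] < pos["PD_E"],
        c_pys_before_lpe=pos["PY_S"] < pos["LP_E"],
        c_lpe_before_pye=pos["LP_E"] < pos["PY_E"],
    )


def enumerate_orderings():
    """All 120 LP_S-anchored orderings and the pyloric subset.

    Returns (orderings, pyloric) where ``orderings`` maps each ordering tuple
    to its :class:`CriteriaFlags` and ``pyloric`` is the list of orderings
    satisfying all three criteria.
    """
    rest = [e for e in EVENTS if e != "LP_S"]
    orderings = {}
    for perm in itertools.permutations(rest):
        seq = ("LP_S",) + perm
        orderings[seq] = ordering_criteria(seq)
    pyloric = [seq for seq, c in orderings.items() if c.all()]
    return orderings, pyloric


def _value_at(trajectory, column, t):
    return float(np.interp(t, trajectory.times, trajectory.outputs[:, column]))


def evaluate_criteria(
    bursts: dict[str, BurstTrain],
    period: float | None,
    trajectory: Trajectory,
    threshold: float = 0.5,
    min_gap: float = 0.0,
) -> tuple[CriteriaFlags, int]:
    """Evaluate the three pyloric criteria and count bursting neurons.

    ``c_gap`` is an instantaneous test at LP burst onset: both PY and PD
    outputs must be below threshold there (and throughout the ``min_gap``
    window before it, if configured).  Flags are False whenever the rhythm is
    undefined.
    """
    n_bursting = sum(bursts[n].crosses_both_ways for n in NEURONS)
    if period is None or n_bursting != 3:
        return NO_CRITERIA, n_bursting
    res = _fold_events(bursts, period, float(trajectory.times[-1]), 0.0)
    if res is None:
        return NO_CRITERIA, n_bursting
    events, anchor, _, _ = res
    gap_times = [anchor] if min_gap <= 0 else list(
        np.linspace(anchor - min_gap, anchor, 8)
    )
    c_gap = all(
        _value_at(trajectory, N_IDX[n], t) < threshold
        for n in ("PY", "PD")
        for t in gap_times
    )
    return (
        CriteriaFlags(
            c_gap=c_gap,
            c_pys_before_lpe=events["PY_S"] < events["LP_E"],
            c_lpe_before_pye=events["LP_E"] < events["PY_E"],
        ),
        n_bursting,
    )


def timing_metrics(bursts: dict[str, BurstTrain], period: float, t_end: float | None = None):
    """Duty cycles and PD-referenced start phases for a folded cycle.

    Returns (duty, phase) dicts, or ``None`` if any neuron lacks exactly one
    burst per cycle.  Phases are defined for all neurons; ``phase["PD"]`` is
    identically 0.
    """
    if t_end is None:
        t_end = max(
            (tr.down_crossings[-1] for tr in bursts.values() if len(tr.down_crossings)),
            default=0.0,
        )
    res = _fold_events(bursts, period, t_end, 0.0)
    if res is None:
        return None
    events, _, local_T, _ = res
    duty = {}
    phase = {}
    pd_start = events["PD_S"]
    for n in NEURONS:
        duty[n] = ((events[f"{n}_E"] - events[f"{n}_S"]) % local_T) / local_T
        phase[n] = ((events[f"{n}_S"] - pd_start) % local_T) / local_T
    return duty, phase


def _piecewise_linear_mean(times, values, a, b):
    """Exact mean of the piecewise-linear interpolant of (times, values) over [a, b]."""
    grid = times[(times > a) & (times < b)]
    knots = np.concatenate(([a], grid, [b]))
    vals = np.vstack([np.interp(knots, times, values[:, i]) for i in range(values.shape[1])]).T
    seg = np.diff(knots)
    mids = 0.5 * (vals[1:] + vals[:-1])
    return (seg[:, None] * mids).sum(axis=0) / (b - a)


def cycle_average(
    trajectory: Trajectory,
    period: float | None = None,
    window: float = 50.0,
) -> dict[str, float]:
    """Trapezoidal mean output per neuron over one cycle (or a trailing window).

    When ``period`` is given the mean is taken over exactly one period ending
    at the last sample; otherwise over the trailing ``window`` seconds
    (clipped to the record), the convention for non-oscillatory circuits.
    """
    t_end = float(trajectory.times[-1])
    span = period if period is not None else min(window, trajectory.duration)
    a = max(t_end - span, float(trajectory.times[0]))
    means = _piecewise_linear_mean(trajectory.times, trajectory.outputs, a, t_end)
    return {n: float(means[i]) for i, n in enumerate(NEURONS)}


@dataclass(frozen=True)
class RhythmDescriptor:
    """Full parse of a post-transient trajectory."""

    period: float | None
    ordering: tuple[str, ...] | None
    n_bursting: int
    criteria: CriteriaFlags
    duty: dict[str, float] | None
    phase: dict[str, float] | None
    averages: dict[str, float]
    pyloric: bool
    oscillatory: bool

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "ordering": list(self.ordering) if self.ordering else None,
            "n_bursting": self.n_bursting,
            "criteria": {
                "c_gap": self.criteria.c_gap,
                "c_pys_before_lpe": self.criteria.c_pys_before_lpe,
                "c_lpe_before_pye": self.criteria.c_lpe_before_pye,
            },
            "duty": self.duty,
            "phase": self.phase,
            "averages": self.averages,
            "pyloric": self.pyloric,
            "oscillatory": self.oscillatory,
        }


def analyze(
    trajectory: Trajectory,
    threshold: float = 0.5,
    min_gap: float = 0.0,
    tie_tol: float | None = None,
) -> RhythmDescriptor:
    """Parse a trajectory into a :class:`RhythmDescriptor`.

    ``tie_tol`` defaults to the sample step; events closer than this are
    treated as ties and leave the ordering undefined (conservatively
    non-pyloric).
    """
    if tie_tol is None:
        tie_tol = trajectory.dt
    trains = parse_bursts(trajectory, threshold)
    period = detect_period(trajectory, threshold)
    osc_period = period if period is not None else _state_period(trajectory)
    criteria, n_bursting = evaluate_criteria(trains, period, trajectory, threshold, min_gap)
    ordering = None
    duty = phase = None
    if period is not None and n_bursting == 3:
        ordering = classify_ordering(
            trains, period, float(trajectory.times[-1]), tie_tol
        )
        tm = timing_metrics(trains, period, float(trajectory.times[-1]))
        if tm is not None:
            duty, phase = tm
    averages = cycle_average(trajectory, osc_period)
    pyloric = n_bursting == 3 and criteria.all() and ordering is not None
    return RhythmDescriptor(
        period=period,
        ordering=ordering,
        n_bursting=n_bursting,
        criteria=criteria,
        duty=duty,
        phase=phase,
        averages=averages,
        pyloric=pyloric,
        oscillatory=osc_period is not None,
    )
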