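"""Grid scans of regulated bias subspaces and endpoint prediction.

The slow regulation dynamics are approximated by cycle-averaging the
regulation drive over the fast rhythm at frozen parameters.  Scanning the
regulated bias axes yields, per grid cell, cycle-averaged outputs and
pyloric status; nullclines of the averaged flow then predict where
regulation settles, and the distribution of averages among pyloric and
non-pyloric cells decides whether any reliable regulator can exist at all.

Sign conventions: the averaged flow for a regulated neuron is
``F = mean(rho(o))`` over one rhythm cycle (``B - o_mean`` for a zero-width
target).  A nullcline crossing is stable when F passes from positive to
negative with increasing bias, equivalently when the cycle-averaged output
increases with the neuron's own bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .adhp import ADHPMechanism, rho
from .ctrnn import (
    BIAS_RANGE,
    NEURONS,
    N_IDX,
    CircuitParams,
    IntegrationError,
    SimulationConfig,
    integrate,
)
from .fitness import evaluate_circuit
from .rhythm import analyze

__all__ = [
    "GridScan",
    "EndpointPrediction",
    "PredictionReport",
    "SeparabilityReport",
    "GeneralizationReport",
    "scan_subspace",
    "flow_field",
    "flow_sign",
    "nullclines",
    "predict_endpoints",
    "separability",
    "generalization",
    "simulated_recovery",
    "predict_vs_simulate",
    "reliable_targets",
]


@dataclass(frozen=True)
class GridScan:
    """Cycle-averaged map of an ADHP-accessible bias subspace.

    Arrays are indexed by one grid dimension per regulated axis (in ``axes``
    order), cells addressable by integer index or bias value via
    :meth:`theta_at`.  ``quantiles`` holds equal-time output quantiles over
    the averaging window, sufficient to evaluate the averaged regulation
    drive of any target range without re-simulation.
    """

    axes: tuple[str, ...]
    grid: tuple[np.ndarray, ...]
    base: CircuitParams
    o_mean: np.ndarray  # shape + (3,)
    quantiles: np.ndarray  # shape + (3, K)
    pyloric: np.ndarray  # bool, shape
    oscillatory: np.ndarray  # bool, shape
    period: np.ndarray  # float, NaN where undefined
    threshold: float = 0.5

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.grid)

    def theta_at(self, idx: tuple[int, ...]) -> dict[str, float]:
        return {a: float(self.grid[d][idx[d]]) for d, a in enumerate(self.axes)}

    def cell_index(self, **theta: float) -> tuple[int, ...]:
        return tuple(
            int(np.argmin(np.abs(self.grid[d] - theta[a])))
            for d, a in enumerate(self.axes)
        )

    def stability(self) -> np.ndarray:
        """True where each regulated neuron's average output increases with
        its own bias (the stable flow arrangement) along every axis."""
        ok = np.ones(self.shape, dtype=bool)
        for d, a in enumerate(self.axes):
            grad = np.gradient(self.o_mean[..., N_IDX[a]], self.grid[d], axis=d)
            ok &= grad > 0
        return ok


def scan_subspace(
    circuit: CircuitParams,
    axes: tuple[str, ...] = ("LP", "PD"),
    step: float = 0.25,
    bounds: tuple[float, float] = BIAS_RANGE,
    config: SimulationConfig | None = None,
    n_quantiles: int = 33,
    fallback_window: float = 50.0,
    progress: bool = False,
) -> GridScan:
    """Simulate every cell of a bias grid with other parameters frozen.

    Each cell runs from y = 0 through the configured transient; averages are
    taken over one detected cycle, or over ``fallback_window`` seconds for
    non-oscillatory cells.  Cells that fail to integrate are marked NaN.
    """
    if not axes or any(a not in N_IDX for a in axes):
        raise ValueError(f"axes must be a nonempty subset of {NEURONS}")
    config = config or SimulationConfig()
    grid = tuple(
        np.arange(bounds[0], bounds[1] + step * 0.5, step, dtype=float) for _ in axes
    )
    shape = tuple(len(g) for g in grid)
    o_mean = np.full(shape + (3,), np.nan)
    quantiles = np.full(shape + (3, n_quantiles), np.nan)
    pyloric = np.zeros(shape, dtype=bool)
    oscillatory = np.zeros(shape, dtype=bool)
    period = np.full(shape, np.nan)
    probs = (np.arange(n_quantiles) + 0.5) / n_quantiles

    cells = list(np.ndindex(*shape))
    iterator = cells
    if progress:
        from tqdm import tqdm  # optional diagnostics only

        iterator = tqdm(cells, desc="scan")
    for idx in iterator:
        params = circuit.with_biases(
            **{a: float(grid[d][idx[d]]) for d, a in enumerate(axes)}
        )
        try:
            traj = integrate(params, config=config)
        except IntegrationError:
            continue
        desc = analyze(traj, config.burst_threshold)
        span = desc.period
        if span is None and desc.oscillatory:
            from .rhythm import _state_period

            span = _state_period(traj)
        window = span if span is not None else min(fallback_window, traj.duration)
        sel = traj.times >= traj.times[-1] - window
        o_win = traj.outputs[sel]
        for i in range(3):
            o_mean[idx + (i,)] = desc.averages[NEURONS[i]]
            quantiles[idx + (i,)] = np.quantile(o_win[:, i], probs)
        pyloric[idx] = desc.pyloric
        oscillatory[idx] = desc.oscillatory
        if desc.period is not None:
            period[idx] = desc.period
    return GridScan(
        axes=tuple(axes),
        grid=grid,
        base=circuit,
        o_mean=o_mean,
        quantiles=quantiles,
        pyloric=pyloric,
        oscillatory=oscillatory,
        period=period,
        threshold=config.burst_threshold,
    )


def _check_mechanism_axes(scan: GridScan, mechanism: ADHPMechanism) -> None:
    if set(mechanism.regulated) != set(scan.axes):
        raise ValueError(
            f"mechanism regulates {mechanism.regulated} but scan covers {scan.axes}"
        )


def flow_field(scan: GridScan, mechanism: ADHPMechanism) -> dict[str, np.ndarray]:
    """Cycle-averaged regulation drive per regulated neuron over the grid.

    Zero-width targets use B - o_mean exactly; positive-width ranges average
    rho over the stored output quantiles (equal-time, so the mean over
    quantiles is the time average of rho for instantaneous detection).
    """
    _check_mechanism_axes(scan, mechanism)
    flows = {}
    for a in mechanism.regulated:
        i = N_IDX[a]
        if mechanism.delta[a] == 0.0:
            flows[a] = mechanism.lb[a] - scan.o_mean[..., i]
        else:
            flows[a] = np.mean(
                rho(scan.quantiles[..., i, :], mechanism.lb[a], mechanism.ub(a)),
                axis=-1,
            )
    return flows


def flow_sign(scan: GridScan, mechanism: ADHPMechanism, idx: tuple[int, ...]) -> dict[str, int]:
    """Sign of the averaged drive in one cell, per regulated dimension."""
    flows = flow_field(scan, mechanism)
    return {a: int(np.sign(flows[a][idx])) for a in mechanism.regulated}


def _axis_crossings(F: np.ndarray, d: int):
    """(stable, unstable) cell masks for sign changes of F along dimension d."""
    lo = [slice(None)] * F.ndim
    hi = [slice(None)] * F.ndim
    lo[d] = slice(None, -1)
    hi[d] = slice(1, None)
    lo, hi = tuple(lo), tuple(hi)
    stable_pair = (F[lo] > 0) & (F[hi] <= 0)
    unstable_pair = (F[lo] <= 0) & (F[hi] > 0)
    stable = np.zeros(F.shape, dtype=bool)
    unstable = np.zeros(F.shape, dtype=bool)
    stable[lo] |= stable_pair
    stable[hi] |= stable_pair
    unstable[lo] |= unstable_pair
    unstable[hi] |= unstable_pair
    return stable, unstable


def _boundary_mask(F: np.ndarray, d: int):
    """Cells on the grid edges of dimension d where the flow points outward
    (the bias clip makes the boundary an attracting nullcline there)."""
    mask = np.zeros(F.shape, dtype=bool)
    first = [slice(None)] * F.ndim
    last = [slice(None)] * F.ndim
    first[d] = 0
    last[d] = -1
    mask[tuple(first)] = F[tuple(first)] < 0
    mask[tuple(last)] = F[tuple(last)] > 0
    return mask


def nullclines(scan: GridScan, mechanism: ADHPMechanism):
    """Per-axis stable / unstable / boundary nullcline cell masks."""
    flows = flow_field(scan, mechanism)
    out = {}
    for d, a in enumerate(scan.axes):
        F = flows[a]
        stable, unstable = _axis_crossings(F, d)
        out[a] = {
            "stable": stable,
            "unstable": unstable,
            "boundary": _boundary_mask(F, d),
        }
    return out


@dataclass(frozen=True)
class EndpointPrediction:
    cell: tuple[int, ...]
    theta: dict[str, float]
    pyloric: bool
    oscillatory: bool
    on_boundary: bool
    flipflop_risk: bool
    status_ambiguous: bool = False


@dataclass(frozen=True)
class PredictionReport:
    category: str  # reliable | mixed | fail | no_steady_state
    endpoints: tuple[EndpointPrediction, ...]
    boundary_pinning: bool
    flipflop_risk: bool
    status_ambiguous: bool = False
    mechanism: ADHPMechanism = field(default=None, repr=False)

    @property
    def flagged(self) -> bool:
        return self.boundary_pinning or self.flipflop_risk or self.status_ambiguous


def _flipflop_mask(scan: GridScan, mechanism: ADHPMechanism, jump_tol: float = 0.25):
    """Cells adjacent to a fixed-point discontinuity whose two sides straddle
    a regulated neuron's target range with opposing flow — the regime where
    regulation can flip-flop across a bifurcation instead of settling."""
    risk = np.zeros(scan.shape, dtype=bool)
    fixed = ~scan.oscillatory
    for d in range(len(scan.axes)):
        lo = [slice(None)] * len(scan.shape)
        hi = [slice(None)] * len(scan.shape)
        lo[d] = slice(None, -1)
        hi[d] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        both_fixed = fixed[lo] & fixed[hi]
        for a in mechanism.regulated:
            i = N_IDX[a]
            oa, ob = scan.o_mean[lo + (i,)], scan.o_mean[hi + (i,)]
            jump = np.abs(ob - oa) > jump_tol
            straddle = (np.minimum(oa, ob) < mechanism.lb[a]) & (
                np.maximum(oa, ob) > mechanism.ub(a)
            )
            pair = both_fixed & jump & straddle
            risk[lo] |= pair
            risk[hi] |= pair
    return risk


def predict_endpoints(
    scan: GridScan, mechanism: ADHPMechanism, jump_tol: float = 0.25
) -> PredictionReport:
    """Predict regulation endpoints from nullcline intersections.

    Cells where every regulated dimension has a stable crossing (or an
    attracting boundary) are grouped into connected components, each one a
    predicted endpoint labeled with its cell's pyloric status.  Components on
    an attracting boundary or adjacent to a bifurcation straddle are flagged
    as the anomaly regimes the averaged-flow framework cannot certify.
    """
    _check_mechanism_axes(scan, mechanism)
    flows = flow_field(scan, mechanism)
    per_axis = []
    boundary_any = np.zeros(scan.shape, dtype=bool)
    for d, a in enumerate(scan.axes):
        stable, _ = _axis_crossings(flows[a], d)
        bnd = _boundary_mask(flows[a], d)
        # oblique nullclines with shallow flow can place the two axes'
        # crossing bands in adjacent cells; widen by one cell before
        # intersecting so near-corner intersections are not missed
        per_axis.append(ndimage.binary_dilation(stable | bnd))
        boundary_any |= bnd
    endpoint_mask = np.logical_and.reduce(per_axis)
    risk_mask = _flipflop_mask(scan, mechanism, jump_tol)

    endpoints = []
    if endpoint_mask.any():
        labels, n_comp = ndimage.label(endpoint_mask)
        absF = sum(np.abs(flows[a]) for a in scan.axes)
        grown = ndimage.binary_dilation(risk_mask)
        for comp in range(1, n_comp + 1):
            cells = np.argwhere(labels == comp)
            best = cells[np.argmin([absF[tuple(c)] for c in cells])]
            idx = tuple(int(v) for v in best)
            comp_mask = labels == comp
            # an endpoint whose immediate neighborhood has mixed pyloric
            # status cannot be labeled at grid resolution: the
            # sharp-boundary detection-error regime
            rep_mask = np.zeros(scan.shape, dtype=bool)
            rep_mask[idx] = True
            near_pyl = scan.pyloric[ndimage.binary_dilation(rep_mask)]
            endpoints.append(
                EndpointPrediction(
                    cell=idx,
                    theta=scan.theta_at(idx),
                    pyloric=bool(scan.pyloric[idx]),
                    oscillatory=bool(scan.oscillatory[idx]),
                    on_boundary=bool((comp_mask & boundary_any).any()),
                    flipflop_risk=bool((comp_mask & grown).any()),
                    status_ambiguous=bool(near_pyl.any()) and not bool(near_pyl.all()),
                )
            )
    if not endpoints:
        category = "no_steady_state"
    elif all(e.pyloric for e in endpoints):
        category = "reliable"
    elif any(e.pyloric for e in endpoints):
        category = "mixed"
    else:
        category = "fail"
    return PredictionReport(
        category=category,
        endpoints=tuple(endpoints),
        boundary_pinning=any(e.on_boundary for e in endpoints),
        flipflop_risk=bool(risk_mask.any()) and any(e.flipflop_risk for e in endpoints),
        status_ambiguous=any(e.status_ambiguous for e in endpoints),
        mechanism=mechanism,
    )


@dataclass(frozen=True)
class SeparabilityReport:
    verdict: str  # fully_regulatable | partially_regulatable | unregulatable
    resolution: float
    exclusive_bins: frozenset
    pyloric_stable_bins: frozenset
    n_pyloric_cells: int
    n_stable_pyloric_cells: int


def _segment_bins(p, q, resolution):
    """Bin keys rasterized along the segment between two average points."""
    p = np.asarray(p)
    q = np.asarray(q)
    n = int(np.max(np.abs(q - p)) / (0.5 * resolution)) + 2
    pts = p[None, :] + np.linspace(0.0, 1.0, n)[:, None] * (q - p)[None, :]
    return {tuple(k) for k in np.round(pts / resolution).astype(np.int64)}


def separability(
    scan: GridScan,
    resolution: float = 0.01,
    interpolate: bool = True,
    jump_cap: float = 0.2,
    boundary_fill: str = "half",
) -> SeparabilityReport:
    """Regulatability verdict from the binned distribution of averages.

    Averages of the regulated neurons are rounded to ``resolution``; a bin
    occupied exclusively by pyloric cells, at least one of them stable,
    certifies that a zero-range mechanism targeting it regulates reliably.

    With ``interpolate`` (default), the non-pyloric region's footprint also
    covers the averages interpolated between adjacent non-pyloric cells
    (and segments toward adjacent pyloric cells: the near half with
    ``boundary_fill="half"``, the whole segment with ``"full"``), a continuum
    correction for desk-scale grids; segments jumping by more than
    ``jump_cap`` per neuron are treated as discontinuities and not filled.
    """
    reg_cols = [N_IDX[a] for a in scan.axes]
    o = scan.o_mean[..., reg_cols].reshape(-1, len(reg_cols))
    valid = np.all(np.isfinite(o), axis=1)
    keys = np.round(o / resolution).astype(np.int64)
    pyl = scan.pyloric.reshape(-1)
    stable = scan.stability().reshape(-1)

    bin_all_pyloric: dict[tuple, bool] = {}
    bin_has_stable_pyl: dict[tuple, bool] = {}
    for k in range(len(keys)):
        if not valid[k]:
            continue
        key = tuple(keys[k])
        bin_all_pyloric[key] = bin_all_pyloric.get(key, True) and bool(pyl[k])
        bin_has_stable_pyl[key] = bin_has_stable_pyl.get(key, False) or bool(
            pyl[k] and stable[k]
        )

    contaminated: set[tuple] = set()
    if interpolate:
        shape = scan.shape
        o_grid = scan.o_mean[..., reg_cols]
        pyl_grid = scan.pyloric
        valid_grid = np.all(np.isfinite(o_grid), axis=-1)
        for d in range(len(shape)):
            for idx in np.ndindex(*shape):
                if idx[d] + 1 >= shape[d]:
                    continue
                jdx = idx[:d] + (idx[d] + 1,) + idx[d + 1 :]
                if not (valid_grid[idx] and valid_grid[jdx]):
                    continue
                a, b = o_grid[idx], o_grid[jdx]
                if np.max(np.abs(b - a)) > jump_cap:
                    continue  # bifurcation-scale jump: no continuum between
                pa, pb = bool(pyl_grid[idx]), bool(pyl_grid[jdx])
                if not pa and not pb:
                    contaminated |= _segment_bins(a, b, resolution)
                elif pa != pb:
                    npy = b if not pb else a
                    other = a if not pb else b
                    far = other if boundary_fill == "full" else 0.5 * (npy + other)
                    contaminated |= _segment_bins(npy, far, resolution)

    exclusive = frozenset(
        key
        for key, all_p in bin_all_pyloric.items()
        if all_p and bin_has_stable_pyl[key] and key not in contaminated
    )
    pyloric_stable = frozenset(key for key, v in bin_has_stable_pyl.items() if v)
    if exclusive:
        verdict = "fully_regulatable"
    elif pyloric_stable:
        verdict = "partially_regulatable"
    else:
        verdict = "unregulatable"
    return SeparabilityReport(
        verdict=verdict,
        resolution=resolution,
        exclusive_bins=exclusive,
        pyloric_stable_bins=pyloric_stable,
        n_pyloric_cells=int((pyl & valid).sum()),
        n_stable_pyloric_cells=int((pyl & stable & valid).sum()),
    )


@dataclass(frozen=True)
class GeneralizationReport:
    category: str  # mutual | partial | none
    overlap_bins: frozenset
    report_a: SeparabilityReport
    report_b: SeparabilityReport


def generalization(
    scan_a: GridScan, scan_b: GridScan, resolution: float = 0.01
) -> GeneralizationReport:
    """Can one zero-range mechanism serve two circuits?

    Mutual when the exclusively-pyloric bin sets intersect; partial when a
    reliable target for one circuit at least reaches the pyloric region of
    the other; none otherwise.
    """
    if scan_a.axes != scan_b.axes:
        raise ValueError(f"scan axes differ: {scan_a.axes} vs {scan_b.axes}")
    ra = separability(scan_a, resolution)
    rb = separability(scan_b, resolution)
    mutual = ra.exclusive_bins & rb.exclusive_bins
    if mutual:
        category = "mutual"
    elif (ra.exclusive_bins & rb.pyloric_stable_bins) or (
        rb.exclusive_bins & ra.pyloric_stable_bins
    ):
        category = "partial"
    else:
        category = "none"
    return GeneralizationReport(
        category=category, overlap_bins=frozenset(mutual), report_a=ra, report_b=rb
    )


def simulated_recovery(
    circuit: CircuitParams,
    mechanism: ADHPMechanism,
    perturb_values: tuple[float, ...] = (-10.0, -5.0, 0.0, 5.0, 10.0),
    duration: float = 50_000.0,
    config: SimulationConfig | None = None,
    settle_tol: float = 0.02,
    settle_window: float = 2000.0,
) -> tuple[int, int]:
    """Count perturbations from which regulation restores pyloricness.

    Perturbs the regulated biases to every point of the grid, runs regulation
    for ``duration`` seconds (with early exit once biases settle), and checks
    pyloricness of the frozen terminal circuit.
    """
    from .adhp import batch_recover

    config = config or SimulationConfig()
    points = list(itertools.product(perturb_values, repeat=len(mechanism.regulated)))
    perturbations = [dict(zip(mechanism.regulated, p)) for p in points]
    try:
        finals = batch_recover(
            circuit,
            mechanism,
            perturbations,
            duration=duration,
            config=config,
            settle_tol=settle_tol,
            settle_window=settle_window,
        )
    except IntegrationError:
        return 0, len(points)
    recovered = sum(int(evaluate_circuit(f, config).pyloric) for f in finals)
    return recovered, len(points)


def predict_vs_simulate(
    circuit: CircuitParams,
    scan: GridScan,
    targets: np.ndarray | None = None,
    tau_theta: float = 150.0,
    perturb_values: tuple[float, ...] = (-10.0, -5.0, 0.0, 5.0, 10.0),
    duration: float = 50_000.0,
    config: SimulationConfig | None = None,
    settle_tol: float = 0.05,
    settle_window: float = 1000.0,
    progress: bool = False,
) -> dict:
    """Compare predicted categories with simulated recovery over a target lattice.

    For every zero-range target combination, predicts the outcome category
    from the scan and measures the simulated recovery fraction from the
    perturbation grid.  Rows flagged for the anomaly regimes (boundary
    pinning, bifurcation flip-flop risk) are reported separately and excluded
    from the agreement rate.
    """
    if targets is None:
        targets = np.linspace(0.0, 1.0, 11)
    config = config or SimulationConfig()
    combos = list(itertools.product(targets, repeat=len(scan.axes)))
    if progress:
        from tqdm import tqdm

        combos = list(tqdm(combos, desc="targets"))
    rows = []
    for combo in combos:
        mech = ADHPMechanism.zero_range(
            dict(zip(scan.axes, combo)), tau_theta=tau_theta
        )
        report = predict_endpoints(scan, mech)
        n_rec, n_tot = simulated_recovery(
            circuit,
            mech,
            perturb_values,
            duration,
            config,
            settle_tol=settle_tol,
            settle_window=settle_window,
        )
        if n_rec == n_tot:
            sim_cat = "reliable"
        elif n_rec == 0:
            sim_cat = "fail"
        else:
            sim_cat = "mixed"
        agree = report.category == sim_cat or (
            report.category == "no_steady_state" and sim_cat == "fail"
        )
        rows.append(
            {
                "targets": dict(zip(scan.axes, map(float, combo))),
                "predicted": report.category,
                "recovered": n_rec,
                "tested": n_tot,
                "simulated": sim_cat,
                "flagged": report.flagged,
                "boundary_pinning": report.boundary_pinning,
                "flipflop_risk": report.flipflop_risk,
                "status_ambiguous": report.status_ambiguous,
                "agree": agree,
            }
        )
    unflagged = [r for r in rows if not r["flagged"]]
    flagged = [r for r in rows if r["flagged"]]
    agreement = (
        sum(r["agree"] for r in unflagged) / len(unflagged) if unflagged else float("nan")
    )
    return {
        "rows": rows,
        "agreement": agreement,
        "n_unflagged": len(unflagged),
        "n_flagged": len(flagged),
        "flagged_rows": flagged,
    }


def reliable_targets(
    scan: GridScan,
    resolution: float = 0.01,
    max_candidates: int = 20,
    tau_theta: float = 150.0,
):
    """Exclusive-bin targets whose endpoint prediction is an unflagged
    'reliable': the certified candidates for fully restoring the rhythm.

    Yields (targets dict, PredictionReport) pairs, at most ``max_candidates``,
    scanning the exclusive bins from the middle outward.
    """
    rep = separability(scan, resolution)
    keys = sorted(rep.exclusive_bins)
    mid = len(keys) // 2
    order = sorted(range(len(keys)), key=lambda i: abs(i - mid))
    found = 0
    for i in order:
        if found >= max_candidates:
            return
        targets = {a: k * resolution for a, k in zip(scan.axes, keys[i])}
        report = predict_endpoints(scan, ADHPMechanism.zero_range(targets, tau_theta))
        if report.category == "reliable" and not report.flagged:
            found += 1
            yield targets, report
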