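import numpy as np
import pytest

from pyloricnet import SimulationConfig
from pyloricnet.adhp import ADHPMechanism, rho
from pyloricnet.ctrnn import N_IDX, logit, sigma
from pyloricnet.fixtures import zero_weight_circuit
from pyloricnet.prediction import (
    GridScan,
    flow_field,
    flow_sign,
    generalization,
    nullclines,
    predict_endpoints,
    predict_vs_simulate,
    scan_subspace,
    separability,
    simulated_recovery,
)


def synthetic_scan(o_lp, o_pd, pyloric, grid_lp, grid_pd, o_py=None, oscillatory=None):
    """Assemble a GridScan from handcrafted 2D average fields (LP, PD axes)."""
    shape = (len(grid_lp), len(grid_pd))
    o_mean = np.zeros(shape + (3,))
    o_mean[..., N_IDX["LP"]] = o_lp
    o_mean[..., N_IDX["PD"]] = o_pd
    o_mean[..., N_IDX["PY"]] = 0.5 if o_py is None else o_py
    K = 9
    quantiles = np.repeat(o_mean[..., None], K, axis=-1)  # fixed points
    return GridScan(
        axes=("LP", "PD"),
        grid=(np.asarray(grid_lp, float), np.asarray(grid_pd, float)),
        base=zero_weight_circuit(),
        o_mean=o_mean,
        quantiles=quantiles,
        pyloric=np.asarray(pyloric, bool),
        oscillatory=(
            np.zeros(shape, bool) if oscillatory is None else np.asarray(oscillatory)
        ),
        period=np.full(shape, np.nan),
    )


def monotone_scan(n=9, pyloric_box=None):
    """Averages increase with own bias (stable everywhere); optional pyloric box."""
    g = np.linspace(-16, 16, n)
    o_lp = sigma(g)[:, None] * np.ones((1, n))
    o_pd = np.ones((n, 1)) * sigma(g)[None, :]
    pyl = np.zeros((n, n), bool)
    if pyloric_box:
        i0, i1, j0, j1 = pyloric_box
        pyl[i0:i1, j0:j1] = True
    return synthetic_scan(o_lp, o_pd, pyl, g, g)


class TestZeroWeightClosedForms:
    def test_scan_averages_exact(self, zero_circuit):
        scan = scan_subspace(
            zero_circuit, ("LP", "PD"), step=8.0, config=SimulationConfig(dt=0.05)
        )
        for idx in np.ndindex(*scan.shape):
            theta = scan.theta_at(idx)
            assert scan.o_mean[idx + (N_IDX["LP"],)] == pytest.approx(
                sigma(theta["LP"]), abs=1e-6
            )
            assert scan.o_mean[idx + (N_IDX["PD"],)] == pytest.approx(
                sigma(theta["PD"]), abs=1e-6
            )
            assert not scan.oscillatory[idx]
            assert not scan.pyloric[idx]

    def test_nullclines_at_logit_of_target(self, zero_circuit):
        scan = scan_subspace(
            zero_circuit, ("LP", "PD"), step=1.0, config=SimulationConfig(dt=0.05)
        )
        mech = ADHPMechanism.zero_range({"LP": 0.3, "PD": 0.7}, tau_theta=150.0)
        nc = nullclines(scan, mech)
        for axis, target in (("LP", 0.3), ("PD", 0.7)):
            d = scan.axes.index(axis)
            cells = np.argwhere(nc[axis]["stable"])
            assert len(cells) > 0
            crossing_thetas = {scan.grid[d][c[d]] for c in cells}
            # stable crossing cells must bracket theta = logit(B)
            assert min(crossing_thetas) <= logit(target) <= max(crossing_thetas)
            assert not nc[axis]["unstable"].any()

    def test_endpoint_at_origin_for_central_targets(self, zero_circuit):
        scan = scan_subspace(
            zero_circuit, ("LP", "PD"), step=1.0, config=SimulationConfig(dt=0.05)
        )
        mech = ADHPMechanism.zero_range({"LP": 0.5, "PD": 0.5}, tau_theta=150.0)
        report = predict_endpoints(scan, mech)
        assert len(report.endpoints) == 1
        ep = report.endpoints[0]
        assert abs(ep.theta["LP"]) <= 0.5
        assert abs(ep.theta["PD"]) <= 0.5
        assert not ep.pyloric  # nothing bursts in an uncoupled net
        assert report.category == "fail"
        assert not report.flagged

    def test_simulation_reaches_predicted_endpoint(self, zero_circuit):
        mech = ADHPMechanism.zero_range({"LP": 0.3, "PD": 0.7}, tau_theta=150.0)
        cfg = SimulationConfig(dt=0.05)
        from pyloricnet.adhp import simulate_with_adhp

        run = simulate_with_adhp(
            zero_circuit, mech, perturbed_biases={"LP": 10.0, "PD": -10.0},
            duration=10_000.0, config=cfg, settle_tol=0.001,
        )
        assert run.final_params.biases["LP"] == pytest.approx(logit(0.3), abs=1e-2)
        assert run.final_params.biases["PD"] == pytest.approx(logit(0.7), abs=1e-2)

    def test_predict_vs_simulate_full_agreement(self, zero_circuit):
        scan = scan_subspace(
            zero_circuit, ("LP", "PD"), step=1.0, config=SimulationConfig(dt=0.05)
        )
        result = predict_vs_simulate(
            zero_circuit,
            scan,
            targets=np.array([0.25, 0.5, 0.75]),
            duration=5000.0,
            config=SimulationConfig(dt=0.05),
        )
        assert result["agreement"] == 1.0


class TestFlow:
    def test_zero_range_flow_is_target_minus_mean(self):
        scan = monotone_scan()
        mech = ADHPMechanism.zero_range({"LP": 0.4, "PD": 0.6}, tau_theta=150.0)
        flows = flow_field(scan, mech)
        assert np.allclose(flows["LP"], 0.4 - scan.o_mean[..., N_IDX["LP"]])
        assert np.allclose(flows["PD"], 0.6 - scan.o_mean[..., N_IDX["PD"]])

    def test_flow_sign_dead_zone_on_fixed_point(self):
        scan = monotone_scan()
        mech = ADHPMechanism(
            regulated=("LP", "PD"),
            lb={"LP": 0.0, "PD": 0.0},
            delta={"LP": 1.0, "PD": 1.0},
            window={"LP": 0.0, "PD": 0.0},
            tau_theta={"LP": 150.0, "PD": 150.0},
        )
        signs = flow_sign(scan, mech, (4, 4))
        assert signs == {"LP": 0, "PD": 0}  # fixed point inside target range

    def test_zero_range_sign_matches_mean_comparison(self):
        scan = monotone_scan()
        mech = ADHPMechanism.zero_range({"LP": 0.6, "PD": 0.6}, tau_theta=150.0)
        lo = scan.cell_index(LP=-8.0, PD=0.0)
        assert flow_sign(scan, mech, lo)["LP"] > 0  # activity below target: bias rises

    def test_wide_range_flow_matches_time_domain_quadrature(self):
        # square-wave output spending fraction f above UB and (1-f) below LB
        f = 0.35
        K = 40
        hi, lo_v = 0.9, 0.1
        n_hi = int(round(f * K))
        q = np.array([lo_v] * (K - n_hi) + [hi] * n_hi)
        scan = monotone_scan()
        quant = np.zeros(scan.shape + (3, K))
        quant[..., :, :] = q  # same distribution in every cell/neuron
        scan = GridScan(
            axes=scan.axes, grid=scan.grid, base=scan.base, o_mean=scan.o_mean,
            quantiles=quant, pyloric=scan.pyloric, oscillatory=scan.oscillatory,
            period=scan.period,
        )
        lb, ub = 0.3, 0.5
        mech = ADHPMechanism(
            regulated=("LP", "PD"),
            lb={"LP": lb, "PD": lb},
            delta={"LP": ub - lb, "PD": ub - lb},
            window={"LP": 0.0, "PD": 0.0},
            tau_theta={"LP": 150.0, "PD": 150.0},
        )
        flows = flow_field(scan, mech)
        expected = (1 - f) * (lb - lo_v) + f * (ub - hi)  # direct rho integral / T
        assert np.allclose(flows["LP"], expected, atol=1e-12)


class TestPredictEndpointsSynthetic:
    def test_reliable_when_only_pyloric_endpoint(self):
        scan = monotone_scan(pyloric_box=(3, 6, 3, 6))
        # target averages attained only inside the pyloric box
        g = scan.grid[0]
        t_lp = float(sigma(g[4]))
        t_pd = float(sigma(g[4]))
        mech = ADHPMechanism.zero_range({"LP": t_lp, "PD": t_pd}, tau_theta=150.0)
        report = predict_endpoints(scan, mech)
        assert report.category == "reliable"
        assert all(e.pyloric for e in report.endpoints)

    def test_fail_when_endpoint_outside(self):
        scan = monotone_scan(pyloric_box=(3, 6, 3, 6))
        g = scan.grid[0]
        mech = ADHPMechanism.zero_range(
            {"LP": float(sigma(g[7])), "PD": float(sigma(g[1]))}, tau_theta=150.0
        )
        report = predict_endpoints(scan, mech)
        assert report.category == "fail"

    def test_no_steady_state_when_targets_unattained(self):
        scan = monotone_scan()
        mech = ADHPMechanism.zero_range({"LP": 1.0, "PD": 0.5}, tau_theta=150.0)
        # target above every attained average and above the boundary value
        # with inward flow at the upper edge... flow at theta=16 is positive
        # so the boundary pins: category is a boundary endpoint, flagged
        report = predict_endpoints(scan, mech)
        assert report.boundary_pinning
        assert all(e.on_boundary for e in report.endpoints)

    def test_unstable_arrangement_yields_no_interior_endpoint(self):
        # averages DECREASE with own bias: every crossing is unstable
        g = np.linspace(-16, 16, 9)
        o_lp = sigma(-g)[:, None] * np.ones((1, 9))
        o_pd = np.ones((9, 1)) * sigma(-g)[None, :]
        scan = synthetic_scan(o_lp, o_pd, np.zeros((9, 9), bool), g, g)
        mech = ADHPMechanism.zero_range({"LP": 0.5, "PD": 0.5}, tau_theta=150.0)
        nc = nullclines(scan, mech)
        assert not nc["LP"]["stable"][1:-1].any()  # interior crossings unstable
        assert nc["LP"]["unstable"].any()

    def test_flipflop_risk_flagged(self):
        # a fixed-point discontinuity straddling the target with opposite flow
        g = np.linspace(-16, 16, 9)
        o_lp = np.where(g < 0, 0.2, 0.8)[:, None] * np.ones((1, 9))
        o_pd = np.ones((9, 1)) * sigma(g)[None, :]
        scan = synthetic_scan(o_lp, o_pd, np.zeros((9, 9), bool), g, g)
        mech = ADHPMechanism.zero_range({"LP": 0.5, "PD": 0.5}, tau_theta=150.0)
        report = predict_endpoints(scan, mech)
        assert report.flipflop_risk


class TestSeparabilitySynthetic:
    def test_fully_regulatable(self):
        scan = monotone_scan(pyloric_box=(3, 6, 3, 6))
        rep = separability(scan)
        assert rep.verdict == "fully_regulatable"
        assert rep.n_stable_pyloric_cells > 0
        assert len(rep.exclusive_bins) > 0

    def test_partially_regulatable_when_averages_duplicated(self):
        # two disjoint theta-regions share identical averages; only one pyloric
        g = np.linspace(-16, 16, 8)
        o_col = np.tile(np.array([0.2, 0.3, 0.4, 0.5, 0.2, 0.3, 0.4, 0.5]), (8, 1)).T
        o_row = np.tile(np.array([0.2, 0.3, 0.4, 0.5, 0.2, 0.3, 0.4, 0.5]), (8, 1))
        pyl = np.zeros((8, 8), bool)
        pyl[1:3, 1:3] = True  # averages there repeat at [5:7, 5:7] (non-pyloric)
        scan = synthetic_scan(o_col, o_row, pyl, g, g)
        rep = separability(scan, interpolate=False)
        assert rep.verdict == "partially_regulatable"
        assert len(rep.exclusive_bins) == 0
        assert len(rep.pyloric_stable_bins) > 0

    def test_unregulatable_when_pyloric_unstable(self):
        g = np.linspace(-16, 16, 9)
        o_lp = sigma(-g)[:, None] * np.ones((1, 9))  # decreasing in own bias
        o_pd = np.ones((9, 1)) * sigma(g)[None, :]
        pyl = np.zeros((9, 9), bool)
        pyl[3:6, 3:6] = True
        scan = synthetic_scan(o_lp, o_pd, pyl, g, g)
        rep = separability(scan)
        assert rep.verdict == "unregulatable"
        assert rep.n_stable_pyloric_cells == 0

    def test_interpolation_contaminates_between_cells(self):
        # pyloric bin value also occurs midway between two non-pyloric cells
        g = np.linspace(-16, 16, 8)
        col = np.array([0.1, 0.2, 0.35, 0.5, 0.6, 0.7, 0.8, 0.9])
        o_lp = np.tile(col, (8, 1)).T
        o_pd = np.tile(col, (8, 1))
        pyl = np.zeros((8, 8), bool)
        pyl[2, 2] = True  # averages (0.35, 0.35)
        # make a remote non-pyloric neighbor pair whose segment passes 0.35
        o_lp[5, 5], o_lp[6, 5] = 0.3, 0.4
        o_pd[5, 5], o_pd[5, 6] = 0.3, 0.4
        o_pd[6, 5] = 0.35
        o_lp[5, 6] = 0.35
        with_interp = separability(synthetic_scan(o_lp, o_pd, pyl, g, g))
        without = separability(
            synthetic_scan(o_lp, o_pd, pyl, g, g), interpolate=False
        )
        assert len(without.exclusive_bins) >= len(with_interp.exclusive_bins)


class TestGeneralizationSynthetic:
    def test_identical_scans_mutual(self):
        scan = monotone_scan(pyloric_box=(3, 6, 3, 6))
        rep = generalization(scan, scan)
        assert rep.category == "mutual"
        assert rep.overlap_bins == rep.report_a.exclusive_bins

    def test_disjoint_exclusive_with_cross_partial(self):
        a = monotone_scan(pyloric_box=(3, 5, 3, 5))
        # same average fields, pyloric region shifted: exclusive sets disjoint,
        # but b's pyloric bins include a's exclusive values
        b = monotone_scan(pyloric_box=(3, 6, 3, 6))
        rep = generalization(a, b)
        assert rep.category in ("mutual", "partial")

    def test_non_generalizable(self):
        a = monotone_scan(pyloric_box=(1, 3, 1, 3))
        b = monotone_scan(pyloric_box=(6, 8, 6, 8))
        rep = generalization(a, b)
        assert rep.category == "none"

    def test_axis_mismatch_rejected(self):
        a = monotone_scan()
        b = GridScan(
            axes=("LP", "PY"), grid=a.grid, base=a.base, o_mean=a.o_mean,
            quantiles=a.quantiles, pyloric=a.pyloric, oscillatory=a.oscillatory,
            period=a.period,
        )
        with pytest.raises(ValueError):
            generalization(a, b)


class TestOnSeparableFixture:
    def test_scan_contains_own_pyloric_cell(self, separable_circuit, separable_scan):
        idx = separable_scan.cell_index(
            LP=separable_circuit.biases["LP"], PD=separable_circuit.biases["PD"]
        )
        assert separable_scan.pyloric[idx]
        # contiguity: the pyloric cell belongs to a region, not an isolated dot
        from scipy import ndimage

        labels, _ = ndimage.label(separable_scan.pyloric)
        assert (labels == labels[idx]).sum() >= 3

    def test_verdict_fully_regulatable(self, separable_scan):
        assert separability(separable_scan).verdict == "fully_regulatable"

    def test_exclusive_target_predicts_reliable_and_simulates(
        self, separable_circuit, separable_scan, fast_config
    ):
        rep = separability(separable_scan)
        key = sorted(rep.exclusive_bins)[len(rep.exclusive_bins) // 2]
        targets = {a: k * rep.resolution for a, k in zip(separable_scan.axes, key)}
        mech = ADHPMechanism.zero_range(targets, tau_theta=150.0)
        report = predict_endpoints(separable_scan, mech)
        assert report.category == "reliable"
        n_rec, n_tot = simulated_recovery(
            separable_circuit, mech, duration=30_000.0, config=fast_config
        )
        assert n_rec == n_tot == 25

    def test_narrow_range_dominance(self, separable_scan):
        # a wide range adds no oscillatory endpoints beyond those of zero-range
        # mechanisms with targets inside the range
        rep = separability(separable_scan)
        key = sorted(rep.exclusive_bins)[0]
        mid = {a: k * rep.resolution for a, k in zip(separable_scan.axes, key)}
        width = 0.2
        wide = ADHPMechanism(
            regulated=("LP", "PD"),
            lb={a: max(mid[a] - width / 2, 0.0) for a in mid},
            delta={a: width for a in mid},
            window={a: 0.0 for a in mid},
            tau_theta={a: 150.0 for a in mid},
        )
        wide_eps = [
            e for e in predict_endpoints(separable_scan, wide).endpoints if e.oscillatory
        ]
        zero_cells = set()
        for blp in np.linspace(wide.lb["LP"], wide.ub("LP"), 7):
            for bpd in np.linspace(wide.lb["PD"], wide.ub("PD"), 7):
                zr = ADHPMechanism.zero_range(
                    {"LP": float(blp), "PD": float(bpd)}, tau_theta=150.0
                )
                for e in predict_endpoints(separable_scan, zr).endpoints:
                    if e.oscillatory:
                        zero_cells.add(e.cell)
        for e in wide_eps:
            assert any(
                max(abs(a - b) for a, b in zip(e.cell, c)) <= 1 for c in zero_cells
            )

    def test_self_generalization_mutual(self, separable_scan):
        from pyloricnet.prediction import generalization

        rep = generalization(separable_scan, separable_scan)
        assert rep.category == "mutual"
        assert rep.overlap_bins == rep.report_a.exclusive_bins

    def test_scan_determinism(self, separable_circuit, fast_config):
        a = scan_subspace(separable_circuit, ("LP", "PD"), step=4.0, config=fast_config)
        b = scan_subspace(separable_circuit, ("LP", "PD"), step=4.0, config=fast_config)
        assert np.array_equal(a.o_mean, b.o_mean)
        assert np.array_equal(a.pyloric, b.pyloric)

    def test_refinement_consistency(self, separable_circuit, fast_config):
        coarse = scan_subspace(
            separable_circuit, ("LP", "PD"), step=4.0, config=fast_config
        )
        fine = scan_subspace(
            separable_circuit, ("LP", "PD"), step=2.0, config=fast_config
        )
        # coarse cell centers exist in the fine grid: classification must agree
        agree = total = 0
        for idx in np.ndindex(*coarse.shape):
            theta = coarse.theta_at(idx)
            fidx = fine.cell_index(**theta)
            total += 1
            agree += int(coarse.pyloric[idx] == fine.pyloric[fidx])
        assert agree / total >= 0.95  # sharp-boundary cells may flip
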