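"""Dynamic elastic-net solver: objective pieces, adjoint gradient, fits."""

import numpy as np
import pytest

from denet import (
    ConfigurationError,
    ControlGrid,
    HiddenInputTrajectory,
    KnownInput,
    MeasurementSet,
    ObjectiveBreakdown,
    RegularizationConfig,
    compute_auc,
    penalty,
    select_lambdas,
    simulate,
    solve_den,
    weighted_sse,
)
from denet.solver import _Transcription

from conftest import QUICK


class TestWeightedSse:
    def test_perfect_fit_is_zero(self):
        ms = MeasurementSet(np.array([0.0, 1.0]), np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert weighted_sse(ms, ms.observations) == 0.0

    def test_identity_weight_euclidean_norm(self):
        ms = MeasurementSet(np.array([0.0, 1.0]), np.array([[3.0, 4.0], [0.0, 0.0]]))
        assert weighted_sse(ms, np.zeros((2, 2))) == pytest.approx(25.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        obs = rng.normal(size=(5, 2))
        fit = rng.normal(size=(5, 2))
        W = np.empty((5, 2, 2))
        for i in range(5):
            a = rng.normal(size=(2, 2))
            W[i] = a @ a.T  # symmetric PSD
        ms = MeasurementSet(np.arange(5.0), obs, weights=W)
        expected = 0.0
        for i in range(5):
            for j in range(2):
                for k in range(2):
                    expected += (obs[i, j] - fit[i, j]) * W[i][j, k] * (obs[i, k] - fit[i, k])
        assert weighted_sse(ms, fit) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_raises(self):
        ms = MeasurementSet(np.array([0.0, 1.0]), np.zeros((2, 2)))
        with pytest.raises(ConfigurationError):
            weighted_sse(ms, np.zeros((3, 2)))


class TestPenalty:
    def test_zero_input_zero_penalty(self):
        grid = ControlGrid.uniform(0, 2, 4)
        w = HiddenInputTrajectory.zeros(grid, 2)
        assert penalty(w, RegularizationConfig(lambda1=1, lambda2=1)) == (0.0, 0.0)

    def test_constant_one_on_interval(self):
        grid = ControlGrid.uniform(0, 2, 4)
        w = HiddenInputTrajectory(grid, np.ones((5, 1)))
        l1, l2 = penalty(w, RegularizationConfig(lambda1=1.0, lambda2=1.0))
        assert l1 == pytest.approx(2.0)
        assert l2 == pytest.approx(2.0)

    def test_matches_fine_trapezoid_oracle(self):
        """Sign-changing piecewise-linear input vs 10^4-point quadrature."""
        rng = np.random.default_rng(7)
        grid = ControlGrid.uniform(0, 5, 13)
        vals = rng.normal(size=(14, 2))
        w = HiddenInputTrajectory(grid, vals)
        fine = np.linspace(0, 5, 10001)
        wf = w(fine)
        l1_o = np.sum(np.trapezoid(np.abs(wf), fine, axis=0))
        l2_o = np.sum(np.trapezoid(wf ** 2, fine, axis=0))
        l1, l2 = penalty(w, RegularizationConfig(lambda1=1.0, lambda2=1.0))
        assert l1 == pytest.approx(l1_o, rel=1e-6)
        assert l2 == pytest.approx(l2_o, rel=1e-6)

    def test_piecewise_constant_basis(self):
        grid = ControlGrid(np.array([0.0, 1.0, 3.0]), basis="piecewise-constant")
        w = HiddenInputTrajectory(grid, np.array([[2.0], [-1.0], [99.0]]))
        l1, l2 = penalty(w, RegularizationConfig(lambda1=1.0, lambda2=1.0))
        assert l1 == pytest.approx(2.0 + 2.0)   # |2|*1 + |-1|*2
        assert l2 == pytest.approx(4.0 + 2.0)   # 4*1 + 1*2


class TestAdjointGradient:
    def test_matches_finite_differences(self, motifs, u_step):
        """The discrete RK4 adjoint reproduces FD gradients to ~1e-8."""
        m = motifs["feedback"]
        st = np.linspace(0, 12, 7)
        rng = np.random.default_rng(0)
        sim = simulate(m, u_step, st)
        data = MeasurementSet(st, sim.outputs + 0.1 * rng.normal(size=sim.outputs.shape))
        cfg = RegularizationConfig(lambda1=0.03, lambda2=0.01)
        grid = ControlGrid.for_data(data, n_intervals=6)
        tr = _Transcription(m, u_step, data, cfg, grid, np.zeros(3, bool), substeps=2)
        z = np.abs(rng.normal(0, 0.2, 2 * grid.n_knots * 3))
        _, _, _, g = tr.objective(z, x0_nominal=m.initial_state)
        gfd = np.zeros_like(z)
        for i in range(z.size):
            e = np.zeros_like(z)
            e[i] = 1e-6
            fp = tr.objective(z + e, need_grad=False, x0_nominal=m.initial_state)[0]
            fm = tr.objective(z - e, need_grad=False, x0_nominal=m.initial_state)[0]
            gfd[i] = (fp - fm) / 2e-6
        assert np.max(np.abs(g - gfd)) < 1e-7 * max(1.0, np.max(np.abs(gfd)))


class TestSolveDen:
    def test_objective_breakdown_additivity(self, chain3_fit):
        _, sol = chain3_fit
        o = sol.objective
        assert o.total == pytest.approx(o.fit_term + o.l1_term + o.l2_term,
                                        rel=1e-9)
        assert min(o.fit_term, o.l1_term, o.l2_term) >= 0

    def test_breakdown_inconsistency_rejected(self):
        with pytest.raises(ConfigurationError):
            ObjectiveBreakdown(total=1.0, fit_term=0.2, l1_term=0.2, l2_term=0.2,
                               solver_status="optimal")

    def test_large_lambda1_yields_zero_input(self, motifs, u_step,
                                             chain3_pulse_truth, chain3_grid):
        """Beyond a finite threshold the L1 weight pins w to zero and the fit
        equals the nominal model's weighted residual."""
        data = chain3_pulse_truth.measurements
        sol = solve_den(motifs["chain3"], u_step, data,
                        RegularizationConfig(lambda1=1e4, lambda2=0.01),
                        chain3_grid, **QUICK)
        assert compute_auc(sol.hidden_input).total == 0.0
        nominal = simulate(motifs["chain3"], u_step, data.sample_times)
        assert sol.objective.fit_term == pytest.approx(
            weighted_sse(data, nominal.outputs), rel=1e-4)
        # w = 0 beats random feasible perturbations at this lambda1
        tr = _Transcription(motifs["chain3"], u_step, data,
                            RegularizationConfig(lambda1=1e4, lambda2=0.01),
                            chain3_grid, np.zeros(3, bool), 2)
        rng = np.random.default_rng(3)
        f0 = tr.objective(np.zeros(2 * chain3_grid.n_knots * 3), need_grad=False,
                          x0_nominal=motifs["chain3"].initial_state)[0]
        for _ in range(5):
            z = np.abs(rng.normal(0, 0.05, 2 * chain3_grid.n_knots * 3))
            fz = tr.objective(z, need_grad=False,
                              x0_nominal=motifs["chain3"].initial_state)[0]
            assert fz > f0

    def test_mask_contract(self, motifs, u_step, chain3_pulse_truth, chain3_grid):
        sol = solve_den(motifs["chain3"], u_step, chain3_pulse_truth.measurements,
                        RegularizationConfig(lambda1=0.05, lambda2=0.005),
                        chain3_grid, zero_mask=[0, 2], **QUICK)
        assert np.all(sol.hidden_input.values[:, [0, 2]] == 0.0)
        assert np.any(sol.hidden_input.values[:, 1] != 0.0)

    def test_deterministic_given_seed(self, motifs, u_step, noisy_chain3_data):
        data = noisy_chain3_data.measurements
        grid = ControlGrid.for_data(data, n_intervals=12)
        cfg = RegularizationConfig(lambda1=10.0, lambda2=0.5)
        a = solve_den(motifs["chain3"], u_step, data, cfg, grid, seed=4,
                      substeps=2, maxiter=300)
        b = solve_den(motifs["chain3"], u_step, data, cfg, grid, seed=4,
                      substeps=2, maxiter=300)
        assert np.array_equal(a.hidden_input.values, b.hidden_input.values)
        assert a.objective.total == b.objective.total

    def test_state_estimate_reproducible_by_reintegration(self, motifs, u_step,
                                                          chain3_fit):
        """x_hat re-integrates from (model, input, w_hat, x0) alone."""
        _, sol = chain3_fit
        t = sol.state_estimate.times
        re = simulate(motifs["chain3"], u_step, t,
                      hidden_input=sol.hidden_input,
                      x0=sol.diagnostics["x0"])
        scale = max(1.0, np.max(np.abs(sol.state_estimate.states)))
        # agreement limited by the fixed-step transcription error at substeps=2
        assert np.max(np.abs(re.states - sol.state_estimate.states)) < 1e-4 * scale

    def test_refinement_stability(self, motifs, u_step, chain3_pulse_truth):
        """Doubling the control resolution moves each AUC by < 5%."""
        data = chain3_pulse_truth.measurements
        cfg = RegularizationConfig(lambda1=0.05, lambda2=0.005)
        auc = {}
        for n in (12, 24):
            grid = ControlGrid.for_data(data, n_intervals=n)
            sol = solve_den(motifs["chain3"], u_step, data, cfg, grid, **QUICK)
            auc[n] = compute_auc(sol.hidden_input).per_component
        ref = np.maximum(np.abs(auc[24]), 0.05 * np.max(auc[24]))
        assert np.all(np.abs(auc[12] - auc[24]) / ref < 0.05)

    def test_free_initial_state_respects_delta0(self, motifs, u_step,
                                                noisy_chain3_data):
        data = noisy_chain3_data.measurements
        grid = ControlGrid.for_data(data, n_intervals=12)
        cfg = RegularizationConfig(lambda1=10.0, lambda2=0.5, delta0=0.5,
                                   initial_state_policy="free-with-delta0-constraint")
        sol = solve_den(motifs["chain3"], u_step, data, cfg, grid,
                        substeps=2, maxiter=300)
        assert sol.diagnostics["constraints"]["delta0_residual"] > -1e-6

    def test_infeasible_endpoint_constraint_reported(self, motifs, u_step,
                                                     noisy_chain3_data):
        data = noisy_chain3_data.measurements
        grid = ControlGrid.for_data(data, n_intervals=12)
        cfg = RegularizationConfig(lambda1=1e9, lambda2=0.5, deltaN=1e-8)
        sol = solve_den(motifs["chain3"], u_step, data, cfg, grid,
                        substeps=2, maxiter=150)
        assert sol.objective.solver_status == "infeasible"

    def test_missing_delta0_rejected(self):
        with pytest.raises(ConfigurationError):
            RegularizationConfig(initial_state_policy="free-with-delta0-constraint")

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            RegularizationConfig(lambda1=-1.0)


class TestSelectLambdas:
    def test_single_point_grid_returns_it(self, motifs, u_step,
                                          chain3_pulse_truth, chain3_grid):
        l1, l2, report = select_lambdas(
            motifs["chain3"], u_step, chain3_pulse_truth.measurements,
            chain3_grid, [0.05], [0.005], substeps=2, maxiter=200)
        assert (l1, l2) == (0.05, 0.005)
        assert len(report) == 1

    def test_path_monotonicity_and_knee(self, motifs, u_step, noisy_chain3_data):
        """fit non-decreasing and L1 norm non-increasing along the lambda1 path."""
        data = noisy_chain3_data.measurements
        grid = ControlGrid.for_data(data, n_intervals=12)
        l1s = [1.0, 3.0, 10.0, 30.0]
        l1, l2, report = select_lambdas(motifs["chain3"], u_step, data, grid,
                                        l1s, [0.5], substeps=2, maxiter=300)
        report = report.sort_values("lambda1")
        fits = report["fit_term"].to_numpy()
        l1norms = report["l1_norm"].to_numpy()
        assert np.all(np.diff(fits) >= -1e-6 * np.abs(fits[:-1]))
        assert np.all(np.diff(l1norms) <= 1e-6 + 1e-6 * np.abs(l1norms[:-1]))
        # knee rule: the largest lambda1 within 1.1x of the best fit
        ok = fits <= 1.1 * fits.min() + 1e-12
        assert l1 == max(np.array(l1s)[ok])
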