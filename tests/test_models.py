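"""Model container, built-in models and the adaptive simulator."""

import numpy as np
import pytest
import sympy as sp
from scipy.linalg import expm

from denet import (
    ConfigurationError,
    KnownInput,
    MeasurementSet,
    OdeModel,
    jak_stat_model,
    linearize,
    model_from_config,
    motif_models,
    simulate,
    uvb_model,
)


class TestKnownInput:
    def test_linear_interpolation_and_constant_hold(self):
        u = KnownInput(np.array([0.0, 1.0, 2.0]), np.array([[0.0], [2.0], [1.0]]))
        assert u(0.5) == pytest.approx([1.0])
        assert u(1.5) == pytest.approx([1.5])
        # boundary values held outside the tabulated range
        assert u(-3.0) == pytest.approx([0.0])
        assert u(10.0) == pytest.approx([1.0])

    def test_zero_order_hold(self):
        u = KnownInput(np.array([0.0, 1.0, 2.0]), np.array([[0.0], [2.0], [1.0]]),
                       interpolation="zero-order-hold")
        assert u(0.99) == pytest.approx([0.0])
        assert u(1.0) == pytest.approx([2.0])

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ConfigurationError):
            KnownInput(np.array([0.0, 2.0, 1.0]), np.zeros((3, 1)))


class TestSimulate:
    def test_scalar_decay_matches_closed_form(self, scalar_decay):
        t = np.linspace(0, 5, 26)
        res = simulate(scalar_decay, None, t)
        assert np.max(np.abs(res.states[:, 0] - np.exp(-t))) < 1e-6

    def test_hidden_input_zero_is_identity(self, motifs, u_step):
        t = np.linspace(0, 12, 25)
        a = simulate(motifs["chain3"], u_step, t)
        b = simulate(motifs["chain3"], u_step, t,
                     hidden_input=lambda tt: np.zeros(3))
        assert np.allclose(a.states, b.states, atol=1e-9)

    def test_outputs_consistent_with_output_function(self, motifs, u_step):
        m = motifs["feedforward"]
        res = simulate(m, u_step, np.linspace(0, 12, 13))
        expected = np.vstack([m.h(x) for x in res.states])
        assert np.array_equal(res.outputs, expected)

    def test_tolerance_halving_changes_little(self, motifs, u_step):
        t = np.linspace(0, 12, 25)
        coarse = simulate(motifs["feedback"], u_step, t, rtol=1e-6, atol=1e-8)
        fine = simulate(motifs["feedback"], u_step, t, rtol=1e-9, atol=1e-11)
        assert np.max(np.abs(coarse.states - fine.states)) < 1e-5

    def test_dimension_mismatch_raises(self, motifs, u_step):
        with pytest.raises(ConfigurationError):
            simulate(motifs["chain3"], u_step, np.linspace(0, 12, 5),
                     hidden_input=lambda t: np.zeros(7))

    def test_superposition_on_linear_motif(self, motifs, u_step):
        """Hidden-input responses superpose on a linear model."""
        t = np.linspace(0, 12, 25)
        m = motifs["chain3"]
        w1 = lambda tt: np.array([0.5, 0.0, 0.0])
        w2 = lambda tt: np.array([0.0, np.sin(0.5 * tt), 0.0])
        w12 = lambda tt: w1(tt) + w2(tt)
        s0 = simulate(m, u_step, t).states
        s1 = simulate(m, u_step, t, hidden_input=w1).states
        s2 = simulate(m, u_step, t, hidden_input=w2).states
        s12 = simulate(m, u_step, t, hidden_input=w12).states
        assert np.max(np.abs(s1 + s2 - s0 - s12)) < 1e-6


class TestJakStat:
    def test_constant_without_receptor_activation(self):
        m = jak_stat_model()
        res = simulate(m, None, np.linspace(0, 60, 13))
        assert np.max(np.abs(res.states - m.initial_state)) < 1e-10

    def test_monomer_total_conserved_symbolically(self):
        """d/dt (x1 + x2 + 2 x3 + 2 x4) vanishes identically."""
        m = jak_stat_model()
        xs = m.sym_states
        conserved = xs[0] + xs[1] + 2 * xs[2] + 2 * xs[3]
        ddt = sum(sp.diff(conserved, x) * r for x, r in zip(xs, m.sym_rates))
        assert sp.simplify(ddt) == 0

    def test_monomer_total_conserved_along_trajectory(self):
        m = jak_stat_model()
        u = KnownInput(np.array([0.0, 10.0, 60.0]),
                       np.array([[1.0], [0.5], [0.1]]))
        res = simulate(m, u, np.linspace(0, 60, 25))
        total = res.states @ np.array([1.0, 1.0, 2.0, 2.0])
        assert np.max(np.abs(total - total[0])) < 1e-7


class TestUvbSurrogate:
    def test_dimensions(self):
        m = uvb_model()
        assert m.n_states == 11
        # 10 distinct rate constants, one per reaction
        assert sum(1 for k in m.parameters if k.startswith("k")) == 10
        assert m.n_outputs == 5

    def test_finite_on_reference_horizon(self):
        m = uvb_model()
        u = KnownInput(np.array([0.0, 2.0, 2.5, 20.0]),
                       np.array([[0.0], [0.0], [1.0], [1.0]]))
        res = simulate(m, u, np.linspace(0, 20, 41))
        assert np.all(np.isfinite(res.states))

    def test_terminal_nodes_have_no_output_effect(self):
        """Hidden inputs on the two sink states leave every output unchanged."""
        m = uvb_model()
        u = KnownInput(np.array([0.0, 2.0, 2.5, 20.0]),
                       np.array([[0.0], [0.0], [1.0], [1.0]]))
        t = np.linspace(0, 20, 21)
        base = simulate(m, u, t)
        for node in (9, 10):
            w = np.zeros(11)
            w[node] = 0.5
            pert = simulate(m, u, t, hidden_input=lambda tt, w=w: w)
            assert np.max(np.abs(pert.outputs - base.outputs)) < 1e-8


class TestMotifs:
    def test_zero_input_zero_state_stays_zero(self, motifs):
        t = np.linspace(0, 12, 13)
        for m in motifs.values():
            res = simulate(m, None, t, x0=np.zeros(m.n_states))
            assert np.max(np.abs(res.states)) < 1e-12

    def test_chain_step_response_matches_matrix_exponential(self, motifs, u_step):
        """Closed-form linear-systems oracle for the chain motif."""
        m = motifs["chain3"]
        p = m.parameters
        A = np.array([[-p["a1"], 0, 0],
                      [p["a1"], -p["a2"], 0],
                      [0, p["a2"], -p["a3"]]])
        b = np.array([1.0, 0.0, 0.0])
        t = np.linspace(0, 12, 13)
        # x(t) = int_0^t e^{A(t-s)} b ds = A^{-1} (e^{At} - I) b
        Ainv = np.linalg.inv(A)
        expected = np.vstack([Ainv @ (expm(A * ti) - np.eye(3)) @ b for ti in t])
        res = simulate(m, u_step, t)
        assert np.max(np.abs(res.states - expected)) < 1e-7

    @pytest.mark.parametrize("name", ["chain3", "feedforward", "feedback"])
    def test_observable_motifs_pass_rank_test(self, motifs, name):
        """Kalman observability rank of the linearisation is full."""
        m = motifs[name]
        A, C = linearize(m, np.ones(m.n_states), np.array([1.0]))
        rows = [C]
        for _ in range(m.n_states - 1):
            rows.append(rows[-1] @ A)
        assert np.linalg.matrix_rank(np.vstack(rows)) == m.n_states

    def test_symmetric_motif_has_indistinguishable_pair(self, motifs, u_step):
        """Equal hidden inputs to x1 or x2 give identical outputs."""
        m = motifs["symmetric"]
        t = np.linspace(0, 12, 25)
        w1 = lambda tt: np.array([np.sin(0.4 * tt) ** 2, 0.0, 0.0])
        w2 = lambda tt: np.array([0.0, np.sin(0.4 * tt) ** 2, 0.0])
        o1 = simulate(m, u_step, t, hidden_input=w1).outputs
        o2 = simulate(m, u_step, t, hidden_input=w2).outputs
        assert np.max(np.abs(o1 - o2)) < 1e-7


class TestContainers:
    def test_measurementset_weights_from_sds(self):
        st = np.array([0.0, 1.0, 2.0])
        obs = np.zeros((3, 2))
        sds = np.array([[0.1, 0.2]] * 3)
        ms = MeasurementSet(st, obs, sds=sds)
        assert ms.weights[0][0, 0] == pytest.approx(100.0)
        assert ms.weights[0][1, 1] == pytest.approx(25.0)

    def test_asymmetric_weight_rejected(self):
        W = np.tile(np.array([[1.0, 0.5], [0.0, 1.0]]), (2, 1, 1))
        with pytest.raises(ConfigurationError):
            MeasurementSet(np.array([0.0, 1.0]), np.zeros((2, 2)), weights=W)

    def test_model_from_config_roundtrip(self, u_step):
        cfg = {
            "states": ["a", "b"],
            "rates": ["u - r1*a", "r1*a - r2*b"],
            "outputs": ["b"],
            "parameters": {"r1": 1.2, "r2": 0.4},
            "initial_state": [0.0, 0.0],
        }
        m = model_from_config(cfg)
        res = simulate(m, u_step, np.linspace(0, 12, 7))
        assert np.all(np.isfinite(res.outputs))
        with pytest.raises(ConfigurationError):
            model_from_config({"states": ["a"]})

    def test_with_parameters_refreshes_output_map(self):
        m = jak_stat_model()
        m2 = m.with_parameters({"s1": 2.0})
        x = np.array([0.5, 0.2, 0.1, 0.0])
        assert m2.h(x)[0] == pytest.approx(2 * m.h(x)[0])
        with pytest.raises(ConfigurationError):
            m.with_parameters({"nope": 1.0})
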