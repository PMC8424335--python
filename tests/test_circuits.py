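"""Benchmark circuit models, equilibria, linearization, and simulation."""

import numpy as np
import pytest
import scipy.linalg
import sympy as sp

from dsfnet.circuits import (
    IFFL_BASELINE_INPUT,
    CircuitModel,
    OperatingPoint,
    StepDesign,
    builtin_model,
    find_equilibrium,
    generate_experiments,
    iffl_study_designs,
    linearize,
    simulate,
)
from dsfnet.dsf_core import derive_dsf, structure_report


def linear_test_model():
    """A 3-state linear circuit (2 measured) for closed-form checks."""
    x1, x2, x3 = sp.symbols("x1 x2 x3")
    u1, u2 = sp.symbols("u1 u2")
    a = sp.Symbol("a")
    exprs = [-2 * x1 + x3 + u1, -1 * x2 + a * x1 + u2, -3 * x3 + x1]
    return CircuitModel("lin3", ["x1", "x2", "x3"], [0, 1], ["u1", "u2"],
                        {"a": 0.5}, exprs, [x1, x2, x3], [u1, u2])


class TestBuiltins:
    def test_iffl_reference_parameters(self):
        m = builtin_model("iffl_ideal")
        assert m.parameters["rho1"] == 641.4
        assert m.parameters["rho2"] == 585.1
        assert m.parameters["rho3"] == 652.8
        assert m.parameters["alpha1"] == 7.8
        assert m.parameters["delta_m"] == 10.0
        assert m.parameters["k1d"] == 200.0
        assert m.parameters["kMu1"] == 4000.0

    def test_iffl_dimensions(self):
        m = builtin_model("iffl_ideal")
        assert m.n == 6 and m.p == 3 and m.m == 3
        assert m.measured_indices == [0, 1, 2]

    def test_override_reflected_in_vector_field(self):
        m = builtin_model("iffl_ideal", {"rho1": 100.0})
        base = builtin_model("iffl_ideal")
        x = np.array([1.0, 1.0, 1.0, 2.0, 1.0, 1.0])
        u = np.zeros(3)
        # x1-dot = rho1*m1 - degradation; difference isolates rho1*m1
        assert m.f(x, u)[0] - base.f(x, u)[0] == pytest.approx((100 - 641.4) * 2.0)

    def test_unknown_name_and_bad_override(self):
        with pytest.raises(ValueError):
            builtin_model("nonesuch")
        with pytest.raises(ValueError):
            builtin_model("iffl_ideal", {"rho1": -1.0})
        with pytest.raises(KeyError):
            builtin_model("iffl_ideal", {"rho99": 1.0})

    def test_repressilator_cyclic_structure(self):
        m = builtin_model("repressilator3")
        op = find_equilibrium(m, np.zeros(3), x_guess=np.full(6, 5.0))
        rep = structure_report(derive_dsf(linearize(m, op)))
        # influence pattern y1<-y3, y2<-y1, y3<-y2, all repressing
        expected = {(0, 2), (1, 0), (2, 1)}
        got = {(i, j) for i in range(3) for j in range(3) if rep.support[i, j]}
        assert got == expected
        assert all(rep.signs[i, j] == "repressing" for i, j in expected)


class TestEquilibrium:
    def test_linear_system_closed_form(self):
        m = linear_test_model()
        u = np.array([1.0, 2.0])
        op = find_equilibrium(m, u)
        A = m.jac_x(np.zeros(3), u)
        B = m.jac_u(np.zeros(3), u)
        assert np.allclose(op.x, -np.linalg.solve(A, B @ u), atol=1e-9)

    def test_iffl_origin_at_zero_input(self):
        m = builtin_model("iffl_ideal")
        op = find_equilibrium(m, np.zeros(3), x_guess=np.full(6, 0.1))
        assert np.allclose(op.x, 0.0, atol=1e-8)

    def test_iffl_feasible_input_residual_and_hurwitz(self):
        m = builtin_model("iffl_ideal")
        op = find_equilibrium(m, IFFL_BASELINE_INPUT)
        assert op.residual_norm < 1e-9 * (1 + np.max(np.abs(op.x)))
        eigs = np.linalg.eigvals(m.jac_x(op.x, op.u))
        assert np.all(np.real(eigs) < 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            find_equilibrium(builtin_model("iffl_ideal"), [-1.0, 0.0, 0.0])


class TestLinearize:
    def test_linear_model_returns_own_matrices(self):
        m = linear_test_model()
        op = OperatingPoint(np.zeros(3), np.zeros(2), 0.0)
        sys = linearize(m, op)
        # measured-first reordering: states (x1, x2 | x3)
        assert np.allclose(sys.A11, [[-2.0, 0.0], [0.5, -1.0]])
        assert np.allclose(sys.A12, [[1.0], [0.0]])
        assert np.allclose(sys.A21, [[1.0, 0.0]])
        assert np.allclose(sys.A22, [[-3.0]])
        assert np.allclose(sys.B1, np.eye(2))

    def test_fd_and_symbolic_jacobians_agree(self, rng):
        m = builtin_model("iffl_crosstalk")
        x = rng.uniform(0.5, 50.0, size=6)
        u = rng.uniform(0.5, 5.0, size=3)
        scale = np.max(np.abs(m.jac_x(x, u)))
        assert np.allclose(m.jac_x(x, u), m.jac_x_fd(x, u), rtol=1e-6,
                           atol=1e-8 * scale)
        assert np.allclose(m.jac_u(x, u), m.jac_u_fd(x, u), rtol=1e-6,
                           atol=1e-8 * scale)

    def test_non_equilibrium_point_warns_but_works(self):
        m = builtin_model("iffl_ideal")
        op = OperatingPoint(np.full(6, 3.0), np.ones(3), np.inf)
        with pytest.warns(UserWarning, match="non-equilibrium"):
            sys = linearize(m, op)
        assert sys.n == 6


class TestSimulate:
    def test_equilibrium_is_stationary(self):
        m = builtin_model("iffl_ideal")
        op = find_equilibrium(m, IFFL_BASELINE_INPUT)
        t = np.linspace(0, 500.0, 26)
        traj = simulate(m, (np.array([0.0]), np.array([op.u])), op.x, t)
        assert np.allclose(traj.Y, op.x[:3], atol=1e-6)

    def test_scalar_decay_analytic(self):
        x = sp.Symbol("x1")
        u = sp.Symbol("u1")
        m = CircuitModel("decay", ["x1"], [0], ["u1"], {"k": 1.0},
                         [-sp.Symbol("k") * x + 0 * u], [x], [u])
        t = np.linspace(0, 5, 51)
        traj = simulate(m, (np.array([0.0]), np.array([[0.0]])), [1.0], t)
        assert np.allclose(traj.Y[:, 0], np.exp(-t), atol=1e-7)

    def test_linear_system_matches_matrix_exponential(self):
        m = linear_test_model()
        u = np.array([0.5, -0.2])
        x0 = np.array([1.0, -1.0, 0.5])
        t = np.linspace(0, 4, 41)
        traj = simulate(m, (np.array([0.0]), np.array([u])), x0, t)
        A = m.jac_x(x0, u)
        B = m.jac_u(x0, u)
        for k, tk in enumerate(t):
            xk = scipy.linalg.expm(A * tk) @ x0
            if tk > 0:
                xk += np.linalg.solve(A, (scipy.linalg.expm(A * tk)
                                          - np.eye(3))) @ (B @ u)
            assert np.allclose(traj.Y[k], xk[:2], rtol=1e-6, atol=1e-8)


class TestGenerateExperiments:
    design = StepDesign(amplitudes=np.full(3, 0.013),
                        onsets=np.array([2500.0, 10500.0, 18500.0]),
                        dt=50.0, t_end=26500.0,
                        u_baseline=IFFL_BASELINE_INPUT.copy(), mode="serial")

    def test_same_seed_bit_identical(self, iffl_models, iffl_ops):
        m, _ = iffl_models
        op, _ = iffl_ops
        a = generate_experiments(m, self.design, noise_sd=0.02, seed=42,
                                 linearized=True, op=op)
        b = generate_experiments(m, self.design, noise_sd=0.02, seed=42,
                                 linearized=True, op=op)
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert np.array_equal(ta.Y, tb.Y) and np.array_equal(ta.U, tb.U)

    def test_zero_amplitude_constant_at_baseline(self, iffl_models, iffl_ops):
        m, _ = iffl_models
        op, _ = iffl_ops
        d0 = StepDesign(amplitudes=np.zeros(3), onsets=self.design.onsets,
                        dt=50.0, t_end=5000.0,
                        u_baseline=IFFL_BASELINE_INPUT.copy())
        with pytest.warns(UserWarning, match="identifiab"):
            suite = generate_experiments(m, d0, noise_sd=0.0, seed=0,
                                         linearized=True, op=op)
        traj = suite.trajectories[0]
        assert np.allclose(traj.Y, traj.Y[0], atol=1e-9)

    def test_noise_sd_calibration(self, iffl_models, iffl_ops):
        m, _ = iffl_models
        op, _ = iffl_ops
        clean = generate_experiments(m, self.design, noise_sd=0.0, seed=1,
                                     linearized=True, op=op)
        noisy = generate_experiments(m, self.design, noise_sd=0.25, seed=1,
                                     linearized=True, op=op)
        resid = noisy.trajectories[0].Y - clean.trajectories[0].Y
        sd = resid.std(axis=0)
        assert np.all(np.abs(sd - 0.25) < 0.025)

    def test_direct_mode_truth_has_diagonal_P(self, iffl_models, iffl_ops):
        m, _ = iffl_models
        op, _ = iffl_ops
        suite = generate_experiments(m, self.design, seed=0, linearized=True,
                                     op=op)
        P = suite.truth.P
        for i in range(3):
            for j in range(3):
                assert P.entries[i][j].is_zero == (i != j)

    def test_direct_nonlinear_matches_linearized_for_small_steps(
            self, iffl_models, iffl_ops):
        m, _ = iffl_models
        op, _ = iffl_ops
        small = StepDesign(amplitudes=np.full(3, 1e-4),
                           onsets=np.array([500.0, 3500.0, 6500.0]),
                           dt=50.0, t_end=9000.0,
                           u_baseline=IFFL_BASELINE_INPUT.copy())
        lin = generate_experiments(m, small, seed=0, linearized=True, op=op)
        non = generate_experiments(m, small, seed=0, linearized=False, op=op)
        dev = np.max(np.abs(lin.trajectories[0].Y - non.trajectories[0].Y))
        scale = np.max(np.abs(lin.trajectories[0].Y - op.x[:3]))
        assert dev < 0.02 * scale

    def test_study_designs_shape(self):
        designs = iffl_study_designs(n_rep=5)
        assert len(designs) == 5
        assert all(d.input_mode == "direct" and d.mode == "serial"
                   for d in designs)
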