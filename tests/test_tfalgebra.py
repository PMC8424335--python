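"""Rational-function algebra: evaluation, inversion, kernels, and gains."""

import numpy as np
import pytest
import scipy.integrate
import scipy.linalg
import scipy.signal
import sympy as sp

from dsfnet.tfalgebra import (
    PoleProximityError,
    RationalFunction,
    SingularMatrixError,
    TransferMatrix,
    UnstableEntryError,
    h2_norm,
    hinf_norm,
    impulse_kernel,
    tf_eval,
    tm_inverse,
)

RNG = np.random.default_rng(7)


def horner(coeffs, x):
    acc = 0.0 + 0.0j
    for c in coeffs:
        acc = acc * x + c
    return acc


class TestEvaluation:
    def test_constant_entry(self):
        tm = TransferMatrix([[RationalFunction([5.0], [1.0])]])
        assert tf_eval(tm, 2.3 + 1j)[0, 0] == pytest.approx(5.0)

    def test_first_order_lag_at_origin(self):
        rf = RationalFunction([1.0], [1.0, 2.0])
        assert rf(0.0) == pytest.approx(0.5)

    def test_random_matrix_matches_horner_oracle(self):
        ent = [[RationalFunction(RNG.standard_normal(4), RNG.standard_normal(4))
                for _ in range(3)] for _ in range(3)]
        tm = TransferMatrix(ent)
        for _ in range(10):
            s0 = complex(*RNG.standard_normal(2))
            val = tf_eval(tm, s0)
            for i in range(3):
                for j in range(3):
                    e = ent[i][j]
                    expect = horner(e.num, s0) / horner(e.den, s0)
                    assert val[i, j] == pytest.approx(expect, rel=1e-12)

    def test_pole_proximity_reports_entry(self):
        tm = TransferMatrix([[RationalFunction([1.0], [1.0, 2.0])]],
                            ["a"], ["b"])
        with pytest.raises(PoleProximityError, match="a"):
            tf_eval(tm, -2.0)

    def test_eval_respects_sum_and_product(self):
        for _ in range(20):
            f = RationalFunction(RNG.standard_normal(3), RNG.standard_normal(3))
            g = RationalFunction(RNG.standard_normal(2), RNG.standard_normal(3))
            s0 = complex(*RNG.standard_normal(2))
            assert (f + g)(s0) == pytest.approx(f(s0) + g(s0), rel=1e-10)
            assert (f * g)(s0) == pytest.approx(f(s0) * g(s0), rel=1e-10)


class TestInverse:
    def test_identity(self):
        tm = TransferMatrix.identity(3)
        inv = tm_inverse(tm)
        assert np.allclose(tf_eval(inv, 1.7), np.eye(3))

    def test_diagonal_of_lags(self):
        tm = TransferMatrix([
            [RationalFunction([1.0], [1.0, 1.0]), RationalFunction.zero()],
            [RationalFunction.zero(), RationalFunction([1.0], [1.0, 4.0])],
        ])
        inv = tm_inverse(tm)
        assert np.allclose(inv.entries[0][0].num, [1.0, 1.0])
        assert np.allclose(inv.entries[1][1].num, [1.0, 4.0])

    def test_2x2_matches_symbolic_adjugate(self):
        a, b = 0.7, -1.3
        tm = TransferMatrix([
            [RationalFunction.constant(1.0), RationalFunction([a], [1.0, 1.0])],
            [RationalFunction([b], [1.0, 2.0]), RationalFunction.constant(1.0)],
        ])
        inv = tm_inverse(tm)
        s = sp.Symbol("s")
        M = sp.Matrix([[1, a / (s + 1)], [b / (s + 2), 1]])
        Minv = M.inv()
        for _ in range(10):
            s0 = complex(*RNG.standard_normal(2)) + 3.0  # keep clear of poles
            expect = np.array(Minv.subs(s, s0).evalf().tolist(), dtype=complex)
            assert np.allclose(tf_eval(inv, s0), expect, rtol=1e-8)

    def test_singular_matrix_rejected(self):
        one = RationalFunction.constant(1.0)
        tm = TransferMatrix([[one, one], [one, one]])
        with pytest.raises(SingularMatrixError):
            tm_inverse(tm)

    @pytest.mark.parametrize("n", [2, 3])
    def test_product_with_inverse_is_identity(self, n):
        for _ in range(5):
            ent = [[RationalFunction(RNG.standard_normal(2), [1.0, RNG.uniform(1, 3)])
                    for _ in range(n)] for _ in range(n)]
            for i in range(n):
                ent[i][i] = ent[i][i] + 2.0  # diagonal dominance: nonsingular
            tm = TransferMatrix(ent)
            inv = tm_inverse(tm)
            for _ in range(10):
                s0 = complex(RNG.uniform(0.5, 2), RNG.uniform(-1, 1))
                prod = tf_eval(tm, s0) @ tf_eval(inv, s0)
                assert np.linalg.norm(prod - np.eye(n)) < 1e-8


class TestImpulseKernel:
    t = np.linspace(0.02, 8.0, 120)

    def test_two_real_poles_sinh_form(self):
        K, a, b = 3.0, 0.4, 1.1
        rf = RationalFunction([K], np.polymul([1, a], [1, b]))
        got = impulse_kernel(rf, self.t)
        sinh_form = (2 * K / (b - a)) * np.exp(-(a + b) * self.t / 2) \
            * np.sinh((b - a) * self.t / 2)
        assert np.allclose(got, sinh_form, atol=1e-9)

    def test_repeated_pole(self):
        a = 0.8
        rf = RationalFunction([1.0], [1.0, 2 * a, a * a])
        assert np.allclose(impulse_kernel(rf, self.t),
                           self.t * np.exp(-a * self.t), atol=1e-9)

    def test_complex_pair_damped_sinusoid(self):
        sig, om = 0.3, 2.0
        rf = RationalFunction([om], [1.0, 2 * sig, sig**2 + om**2])
        assert np.allclose(impulse_kernel(rf, self.t),
                           np.exp(-sig * self.t) * np.sin(om * self.t), atol=1e-9)

    def test_matches_state_space_simulation_oracle(self):
        # independent oracle: impulse response = C expm(A t) B of a realization
        num = [2.0, 1.0]
        den = [1.0, 2.2, 3.0, 0.9]
        rf = RationalFunction(num, den)
        A, B, C, D = scipy.signal.tf2ss(num, den)
        expect = np.array([float(np.squeeze(C @ scipy.linalg.expm(A * tt) @ B))
                           for tt in self.t])
        assert np.allclose(impulse_kernel(rf, self.t), expect, atol=1e-6)

    def test_kernel_laplace_transform_recovers_rf(self):
        rf = RationalFunction([1.5], np.polymul([1, 0.5], [1, 1.5]))
        T = 10 / 0.5  # >= 10 slowest time constants
        tg = np.linspace(0, T, 6000)
        k = impulse_kernel(rf, tg)
        for s in [0.3, 0.7, 1.1, 2.0, 3.5]:
            val = np.trapezoid(k * np.exp(-s * tg), tg)
            assert val == pytest.approx(rf(s).real, rel=1e-3)

    def test_rejects_non_strictly_proper(self):
        with pytest.raises(ValueError):
            impulse_kernel(RationalFunction([1.0, 0.0], [1.0, 1.0]), self.t)


class TestHinf:
    def test_first_order_dc_peak(self):
        assert hinf_norm(RationalFunction([3.0], [1.0, 2.0])) == pytest.approx(1.5)

    def test_zero_function(self):
        assert hinf_norm(RationalFunction.zero()) == 0.0

    def test_resonant_second_order_matches_dense_sweep(self):
        zeta = 0.1
        rf = RationalFunction([1.0], [1.0, 2 * zeta, 1.0])
        w = np.logspace(-4, 4, 10**6)
        brute = np.max(np.abs(1.0 / (-(w**2) + 2j * zeta * w + 1.0)))
        assert hinf_norm(rf) == pytest.approx(brute, rel=1e-4)

    def test_unstable_entry_rejected(self):
        with pytest.raises(UnstableEntryError):
            hinf_norm(RationalFunction([1.0], [1.0, -1.0]))

    def test_at_least_dc_gain(self):
        for _ in range(20):
            rf = RationalFunction(RNG.standard_normal(2),
                                  [1.0, RNG.uniform(0.5, 3), RNG.uniform(0.5, 3)])
            if not rf.is_stable():
                continue
            assert hinf_norm(rf) >= abs(rf(0.0)) - 1e-12


class TestH2:
    def test_first_order_closed_form(self):
        a = 1.7
        assert h2_norm(RationalFunction([1.0], [1.0, a])) == pytest.approx(
            1.0 / np.sqrt(2 * a))

    def test_zero_function(self):
        assert h2_norm(RationalFunction.zero()) == 0.0

    def test_matches_quadrature_oracle(self):
        rf = RationalFunction([1.0, 2.0, 0.5],
                              np.polymul([1, 0.8, 2.0], [1, 1.3, 0.6]))
        val, _ = scipy.integrate.quad(
            lambda w: abs(rf(1j * w)) ** 2, -np.inf, np.inf, limit=400)
        assert h2_norm(rf) == pytest.approx(np.sqrt(val / (2 * np.pi)), rel=1e-6)

    def test_rejects_biproper_and_unstable(self):
        with pytest.raises(ValueError):
            h2_norm(RationalFunction([1.0, 1.0], [1.0, 2.0]))
        with pytest.raises(UnstableEntryError):
            h2_norm(RationalFunction([1.0], [1.0, -0.5]))


class TestArithmeticProperties:
    """Field-axiom style invariants of the rational arithmetic."""

    from hypothesis import given, settings, strategies as st

    coeffs = st.lists(st.floats(min_value=-5, max_value=5,
                                allow_nan=False, allow_infinity=False),
                      min_size=1, max_size=4)

    @staticmethod
    def _rf(num, den):
        den = np.asarray(den, dtype=float)
        if np.max(np.abs(den)) < 1e-3:
            den = den + 1.0  # keep the denominator well away from zero
        return RationalFunction(np.asarray(num, dtype=float), den)

    @given(coeffs, coeffs, coeffs, coeffs)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_addition_commutes_and_multiplication_distributes(self, na, da,
                                                              nb, db):
        f = self._rf(na, da)
        g = self._rf(nb, db)
        s0 = 0.37 + 0.91j
        try:
            lhs = (f + g)(s0)
            rhs = (g + f)(s0)
            prod = (f * (g + g))(s0)
            expect = 2.0 * f(s0) * g(s0)
        except PoleProximityError:
            return
        scale = max(1.0, abs(lhs), abs(prod))
        assert abs(lhs - rhs) <= 1e-9 * scale
        assert abs(prod - expect) <= 1e-9 * scale

    @given(coeffs, coeffs)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_subtracting_self_yields_zero_function(self, n, dd):
        f = self._rf(n, dd)
        diff = (f - f).cancel()
        assert np.max(np.abs(diff.num)) <= 1e-9 * max(
            1.0, float(np.max(np.abs(f.num))))


class TestNormalization:
    def test_monic_denominator_and_zero_representation(self):
        rf = RationalFunction([2.0], [4.0, 8.0])
        assert np.allclose(rf.den, [1.0, 2.0])
        assert np.allclose(rf.num, [0.5])
        z = RationalFunction([0.0, 0.0], [3.0, 1.0])
        assert z.is_zero and np.allclose(z.num, [0.0]) and np.allclose(z.den, [1.0])

    def test_cancel_removes_common_root(self):
        rf = RationalFunction(np.polymul([1.0, 1.0], [2.0]),
                              np.polymul([1.0, 1.0], [1.0, 3.0]))
        c = rf.cancel()
        assert c.den_degree == 1
        assert c(0.5) == pytest.approx(rf(0.5))
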