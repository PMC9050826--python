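"""Closed-form scalar functions: vector field, eigensystems, limit algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import branchwave as bw
from branchwave import model_core as mc


class TestVectorFieldAndJacobian:
    @pytest.mark.parametrize("K", [0.0, 0.5, 1.0, 2.0, 3.7])
    def test_continuum_of_fixed_points(self, params_c2, K):
        assert np.allclose(bw.vector_field(params_c2, (0.0, 0.0, K)), 0.0)

    def test_direct_substitution(self, params_c2):
        out = bw.vector_field(params_c2, (0.1, 0.0, 0.5))
        assert np.allclose(out, [0.0, -0.04, -0.03])

    @pytest.mark.parametrize("i", [0.2, 0.5, 0.9])
    def test_reduced_fixed_point_not_fixed_in_full_system(self, params_c2, i):
        # at (1-i, 0, i) the b-equation balances but i still drains
        out = bw.vector_field(params_c2, (1.0 - i, 0.0, i))
        assert abs(out[1]) < 1e-14
        expected_di = -(1.0 - i) * (1.0 + params_c2.r) / params_c2.c
        assert out[2] == pytest.approx(expected_di)
        assert out[2] < 0

    def test_rejects_nonfinite_state(self, params_c2):
        with pytest.raises(ValueError):
            bw.vector_field(params_c2, (np.nan, 0.0, 1.0))
        with pytest.raises(ValueError):
            bw.jacobian(params_c2, (np.inf, 0.0, 1.0))

    @pytest.mark.parametrize("K", [0.0, 0.5, 1.5])
    def test_jacobian_rows_at_fixed_point(self, params_c2, K):
        J = bw.jacobian(params_c2, (0.0, 0.0, K))
        c, r = params_c2.c, params_c2.r
        assert np.allclose(J[0], [0.0, 1.0, 0.0])
        assert np.allclose(J[1], [K - 1.0, -c, 0.0])
        assert np.allclose(J[2], [-(K + r) / c, 0.0, 0.0])
        assert np.trace(J) == pytest.approx(-c)

    def test_jacobian_matches_finite_differences(self, rng):
        params = bw.ModelParams(c=1.7, r=0.6)
        h = 1e-5
        for _ in range(100):
            s = rng.uniform(-1.0, 2.0, size=3)
            J = bw.jacobian(params, s)
            J_fd = np.empty((3, 3))
            for k in range(3):
                e = np.zeros(3)
                e[k] = h
                J_fd[:, k] = (
                    bw.vector_field(params, s + e) - bw.vector_field(params, s - e)
                ) / (2 * h)
            assert np.max(np.abs(J - J_fd)) <= 1e-6


class TestParamsValidation:
    @pytest.mark.parametrize("c,r", [(0.0, 0.0), (-1.0, 0.0), (2.0, -0.1)])
    def test_invalid_parameters_rejected(self, c, r):
        with pytest.raises(ValueError):
            bw.ModelParams(c=c, r=r)

    def test_critical_density_examples(self):
        assert bw.critical_density(2.0) == 0.0
        assert bw.critical_density(3.0) == 0.0
        assert bw.critical_density(1.0) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            bw.critical_density(0.0)


class TestEigensystem:
    def test_double_root_at_c2_K0(self, params_c2):
        es = bw.fixed_point_eigensystem(params_c2, 0.0)
        assert es.degenerate and not es.is_complex
        assert es.lambda_plus == pytest.approx(-1.0)
        assert es.lambda_minus == pytest.approx(-1.0)
        assert es.lambda0 == 0.0

    @pytest.mark.parametrize("c", [1.0, 2.0, 3.5])
    def test_K_equal_one(self, c):
        es = bw.fixed_point_eigensystem(bw.ModelParams(c=c), 1.0)
        assert es.lambda_plus == pytest.approx(0.0, abs=1e-14)
        assert es.lambda_minus == pytest.approx(-c)

    def test_c2_K2_roots(self, params_c2):
        es = bw.fixed_point_eigensystem(params_c2, 2.0)
        assert es.lambda_plus == pytest.approx(-1.0 + math.sqrt(2.0))
        assert es.lambda_minus == pytest.approx(-1.0 - math.sqrt(2.0))

    def test_complex_case_flagged(self):
        es = bw.fixed_point_eigensystem(bw.ModelParams(c=1.0), 0.0)
        assert es.is_complex
        assert es.lambda_plus.imag == pytest.approx(math.sqrt(0.75))

    @given(
        c=st.floats(0.3, 5.0),
        K=st.floats(-0.5, 3.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_quadratic_consistency(self, c, K):
        """lambda_pm are the roots of lambda^2 + c lambda - (K - 1)."""
        es = bw.fixed_point_eigensystem(bw.ModelParams(c=c), K)
        for lam in (es.lambda_plus, es.lambda_minus):
            assert abs(lam**2 + c * lam - (K - 1.0)) <= 1e-12

    @pytest.mark.parametrize("K", [0.05, 0.4, 0.8, 1.3, 1.9, 2.5])
    @pytest.mark.parametrize("c", [1.5, 2.0, 3.0])
    def test_eigen_residual(self, c, K):
        params = bw.ModelParams(c=c, r=0.3)
        es = bw.fixed_point_eigensystem(params, K)
        if es.is_complex or es.degenerate:
            # spiraling/degenerate combos: the flag itself is the contract
            assert c * c / 4.0 + K - 1.0 <= mc.ALG_TOL
            return
        J = bw.jacobian(params, (0.0, 0.0, K))
        for lam, v in [
            (es.lambda0, es.vectors[0]),
            (es.lambda_plus, es.vectors[1]),
            (es.lambda_minus, es.vectors[2]),
        ]:
            assert np.linalg.norm(J @ v - np.real(lam) * v) <= 1e-10 * np.linalg.norm(v)


class TestDecayRate:
    def test_subexponential_flag_at_zero_discriminant(self, params_c2):
        mu, kind = bw.decay_rate(params_c2, 0.0)
        assert mu == pytest.approx(-1.0)
        assert kind == "sub-exponential"

    def test_stable_and_unstable_rates(self, params_c2):
        mu, kind = bw.decay_rate(params_c2, 0.2)
        assert kind == "exponential"
        assert mu == pytest.approx(-1.0 + math.sqrt(0.2))
        mu, kind = bw.decay_rate(params_c2, 1.8)
        assert mu == pytest.approx(-1.0 + math.sqrt(1.8))
        assert mu > 0

    def test_spiraling_flag(self):
        mu, kind = bw.decay_rate(bw.ModelParams(c=1.0), 0.5)
        assert kind == "spiraling"
        assert isinstance(mu, complex)

    @pytest.mark.parametrize("K", [0.3, 0.7, 1.2, 2.0])
    def test_matches_lambda_plus(self, params_c2, K):
        mu, _ = bw.decay_rate(params_c2, K)
        es = bw.fixed_point_eigensystem(params_c2, K)
        assert mu == pytest.approx(np.real(es.lambda_plus))


class TestUnstableDirection:
    def test_printed_components_c2_r0_im2(self, params_c2):
        e = bw.unstable_direction(params_c2, 2.0)
        s2 = math.sqrt(2.0)
        assert e[0] == pytest.approx(1.0 + s2)
        assert e[1] == pytest.approx(1.0)
        assert e[2] == pytest.approx((-1.0 - s2) / (-1.0 + s2))

    @pytest.mark.parametrize("im", [1.05, 1.4, 1.8, 2.0])
    @pytest.mark.parametrize("r", [0.0, 1.5])
    def test_sign_structure_and_eigen_residual(self, im, r):
        params = bw.ModelParams(c=2.0, r=r)
        e = bw.unstable_direction(params, im)
        assert e[0] > 0 and e[1] > 0 and e[2] < 0
        J = bw.jacobian(params, (0.0, 0.0, im))
        es = bw.fixed_point_eigensystem(params, im)
        lam = np.real(es.lambda_plus)
        assert np.linalg.norm(J @ e - lam * e) <= 1e-10 * np.linalg.norm(e)

    def test_rejects_stable_side(self, params_c2):
        with pytest.raises(ValueError):
            bw.unstable_direction(params_c2, 0.9)


class TestLimitAlgebra:
    def test_zero_start_is_identity(self, params_c2):
        for i0 in (0.0, 0.3, 0.99):
            assert bw.limit_map(0.0, i0, params_c2) == pytest.approx(i0)

    def test_value_example(self, params_c2):
        val = bw.limit_map(0.1, 0.5, params_c2)
        assert val == pytest.approx(1.0 - math.sqrt(0.3625))

    def test_alpha_examples(self, params_c2):
        assert bw.alpha_threshold(bw.critical_density(2.0), params_c2) == pytest.approx(
            0.0, abs=1e-12
        )
        assert bw.alpha_threshold(0.5, params_c2) == pytest.approx(
            0.8 * (-0.5 + math.sqrt(1.1875))
        )

    @pytest.mark.parametrize("c,r", [(2.0, 0.0), (1.3, 0.0), (2.5, 1.0), (3.0, 0.4)])
    def test_alpha_round_trip(self, c, r):
        params = bw.ModelParams(c=c, r=r)
        ic = bw.critical_density(c)
        for i0 in np.linspace(ic + 1e-3, 0.98, 7):
            a0 = bw.alpha_threshold(float(i0), params)
            assert abs(bw.limit_map(a0, float(i0), params) - ic) <= 1e-10

    def test_a_star(self, params_c2):
        assert bw.a_star(0.5, params_c2) == pytest.approx(
            bw.alpha_threshold(0.5, params_c2)
        )
        for i0 in np.linspace(0.05, 0.95, 9):
            a = bw.a_star(float(i0), params_c2)
            assert 0.0 <= a <= 1.0 - i0 + 1e-15

    @given(i0=st.floats(0.01, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_limit_map_monotone_decreasing_in_a0(self, i0):
        params = bw.ModelParams(c=2.0, r=0.5)
        grid = np.linspace(0.0, 1.0 - i0, 30)
        vals = [bw.limit_map(float(a0), i0, params) for a0 in grid]
        assert all(v1 >= v2 - 1e-12 for v1, v2 in zip(vals, vals[1:]))

    @pytest.mark.parametrize("c,r", [(2.0, 0.0), (2.5, 1.0)])
    def test_limit_map_stays_in_admissible_band(self, c, r):
        params = bw.ModelParams(c=c, r=r)
        ic = bw.critical_density(c)
        for i0 in np.linspace(ic + 0.01, 0.95, 6):
            for frac in np.linspace(0.0, 1.0, 6):
                a0 = frac * bw.a_star(float(i0), params)
                val = bw.limit_map(a0, float(i0), params)
                assert ic - 1e-10 <= val <= i0 + 1e-10

    def test_rejects_out_of_range(self, params_c2):
        with pytest.raises(ValueError):
            bw.alpha_threshold(1.0, params_c2)
        with pytest.raises(ValueError):
            bw.limit_map(-0.1, 0.5, params_c2)


class TestTurningPoint:
    def test_vanishes_at_mirror_equality(self, params_c2):
        # (i_minus_inf - 1)^2 == (1 - i_z0)^2 makes the second radicand term 0
        val = bw.turning_point_active(0.6, 1.4, params_c2)
        assert val == pytest.approx(0.0, abs=1e-14)

    def test_coincides_with_alpha_at_extreme_left_limit(self):
        # i_minus_inf = 2 - i_c turns the closed form into the alpha threshold
        for c in (1.5, 2.0):
            params = bw.ModelParams(c=c, r=0.0)
            ic = bw.critical_density(c)
            iz = 0.7
            assert bw.turning_point_active(iz, 2.0 - ic, params) == pytest.approx(
                bw.alpha_threshold(iz, params)
            )

    def test_rejects_inadmissible_radicand(self, params_c2):
        with pytest.raises(ValueError):
            bw.turning_point_active(0.2, 1.2, params_c2)
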