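"""Cascade stages: filtering, modulation, transfer, pool normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from cortcol import model_core as mc

PARAMS = mc.ModelParams()


class TestLinearFilter:
    def test_zero_input(self):
        assert mc.linear_filter(np.zeros(7), np.ones(7)) == 0.0

    def test_one_hot_kernel_selects_component(self):
        s = np.array([0.3, 0.9, 0.1])
        k = np.array([0.0, 1.0, 0.0])
        assert mc.linear_filter(s, k) == pytest.approx(0.9)

    def test_matches_brute_force_sum(self, rng):
        s = rng.random(10)
        k = rng.random(10)
        brute = sum(float(k[j]) * float(s[j]) for j in range(10))
        assert mc.linear_filter(s, k) == pytest.approx(brute)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mc.linear_filter(np.ones(3), np.ones(4))


class TestModulate:
    def test_zero_drive_gates_any_feedback(self):
        for fb in (0.0, 1.0, 10.0, 1e6):
            assert mc.modulate(0.0, fb) == 0.0

    def test_no_feedback_leaves_signal_unchanged(self):
        assert mc.modulate(0.37, 0.0) == pytest.approx(0.37)

    def test_arithmetic(self):
        assert mc.modulate(2.0, 3.0) == pytest.approx(8.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mc.modulate(-1.0, 0.0)
        with pytest.raises(ValueError):
            mc.modulate(1.0, -0.5)


class TestTransfers:
    def test_rectification(self):
        np.testing.assert_array_equal(
            mc.transfer_u(np.array([-1.0, 0.0, 0.7])), np.array([0.0, 0.0, 0.7])
        )

    def test_logistic_midpoint(self):
        # printed calibration: g_v(700) = 0.5 at kappa = 0.0075, mu = 700
        assert mc.transfer_v(np.array([700.0]), 0.0075, 700.0)[0] == pytest.approx(0.5)

    def test_logistic_limits_and_value(self):
        out = mc.transfer_v(np.array([-1e9, 1e9, 800.0]), 0.0075, 700.0)
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(1.0, abs=1e-12)
        assert out[2] == pytest.approx(1.0 / (1.0 + np.exp(-0.75)))

    def test_logistic_monotone_in_unit_interval(self, rng):
        v = np.sort(rng.normal(700, 300, size=50))
        g = mc.transfer_v(v, 0.0075, 700.0)
        assert np.all(np.diff(g) >= 0)
        assert np.all((g > 0) & (g < 1))


class TestPoolNormalize:
    def test_zero_gain_is_pure_scaling(self, rng):
        raw = rng.random(20)
        out = mc.pool_normalize(raw, alpha=2.0, beta=3.0, pool_gain=0.0, transfer=mc.transfer_u)
        np.testing.assert_allclose(out, 1.5 * raw)

    @pytest.mark.parametrize("r", [0.1, 1.0, 42.0])
    def test_single_unit_matches_scalar_closed_form(self, r):
        # x = beta*r/(alpha + x) has positive root (-alpha + sqrt(alpha^2+4*beta*r))/2
        alpha, beta = 1.0, 1.0
        out = mc.pool_normalize(
            np.array([r]), alpha, beta, pool_gain=1.0, transfer=lambda x: x, tol=1e-12
        )
        expected = (-alpha + np.sqrt(alpha**2 + 4 * beta * r)) / 2
        assert out[0] == pytest.approx(expected, abs=1e-8)

    def test_output_bounded_by_uninhibited_response(self, rng):
        raw = rng.random(30) * 5
        out = mc.pool_normalize(raw, alpha=1.0, beta=2.0, pool_gain=0.05, transfer=mc.transfer_u)
        assert np.all(out >= 0)
        assert np.all(out <= 2.0 * raw + 1e-12)

    def test_negative_raw_rejected(self):
        with pytest.raises(ValueError):
            mc.pool_normalize(np.array([-1.0]), 1.0, 1.0, 0.0, mc.transfer_u)

    def test_nonconvergence_reports_residual(self):
        with pytest.raises(mc.ConvergenceError, match="residual"):
            mc.pool_normalize(
                np.ones(5), 1.0, 1.0, 10.0, mc.transfer_u, tol=1e-16, max_iter=3
            )


class TestLayer2:
    def test_zero_residual_equals_feedforward(self, rng):
        s = rng.random(50)
        np.testing.assert_array_equal(
            mc.layer2_response(s, np.zeros(50), PARAMS),
            mc.layer2_response(s, None, PARAMS),
        )

    @given(hst.floats(min_value=0.0, max_value=1e4))
    def test_gating_asymmetry(self, fb_strength):
        # a silent input pixel stays silent under arbitrary feedback
        s = np.array([0.0, 1.0, 0.5, 0.0])
        res = np.full(4, fb_strength)
        g_u = mc.layer2_response(s, res, PARAMS)
        assert g_u[0] == 0.0
        assert g_u[3] == 0.0

    def test_lambda_zero_ignores_residual(self, rng):
        params = mc.ModelParams(lam=0.0)
        s = rng.random(30)
        res = rng.random(30)
        np.testing.assert_array_equal(
            mc.layer2_response(s, res, params), mc.layer2_response(s, None, params)
        )

    def test_monotone_in_residual(self, rng):
        s = rng.random(30)
        res = np.zeros(30)
        base = mc.layer2_response(s, res, PARAMS)
        res2 = res.copy()
        res2[7] += 0.5
        boosted = mc.layer2_response(s, res2, PARAMS)
        assert boosted[7] >= base[7]

    def test_negative_residual_rejected(self, rng):
        with pytest.raises(ValueError):
            mc.layer2_response(rng.random(5), np.array([0.1, -0.2, 0, 0, 0]), PARAMS)


class TestLayer3:
    def test_silent_layer2_gives_logistic_floor(self):
        w_in = np.full((10, 3), 0.5)
        v, g_v = mc.layer3_response(np.zeros(10), w_in, PARAMS)
        np.testing.assert_array_equal(v, 0.0)
        expected = 1.0 / (1.0 + np.exp(PARAMS.kappa_log * PARAMS.mu_log))
        np.testing.assert_allclose(g_v, expected)

    def test_unit_aligned_weights_recover_norm(self, rng):
        g_u = rng.random(40)
        params = mc.ModelParams(pool_gain_l3=0.0, alpha_v=1.0, beta_v=1.0, beta_u=1.0)
        w_in = (g_u / np.linalg.norm(g_u))[:, None]
        v, _ = mc.layer3_response(g_u, w_in, params)
        assert v[0] == pytest.approx(np.linalg.norm(g_u))

    def test_raw_response_linear_in_weights(self, rng):
        g_u = rng.random(40)
        params = mc.ModelParams(pool_gain_l3=0.0)
        w = rng.random((40, 2))
        w2 = w.copy()
        w2[:, 1] *= 2.0
        v, _ = mc.layer3_response(g_u, w, params)
        v2, _ = mc.layer3_response(g_u, w2, params)
        assert v2[1] == pytest.approx(2.0 * v[1])
        assert v2[0] == pytest.approx(v[0])


class TestWta:
    def test_argmax_and_tie_rule(self):
        assert mc.wta(np.array([0.1, 0.9, 0.3])) == 1
        assert mc.wta(np.array([0.4, 0.4, 0.4])) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mc.wta(np.array([]))

    @given(hst.permutations(list(range(6))))
    def test_permutation_consistency(self, perm):
        values = np.array([0.05, 0.1, 0.2, 0.4, 0.8, 0.9])
        permuted = values[list(perm)]
        brute = max(range(6), key=lambda i: permuted[i])
        assert mc.wta(permuted) == brute


class TestResidualTemplate:
    def test_perfect_prediction_zeroes_residual(self, rng):
        g_u = rng.random(20)
        np.testing.assert_array_equal(mc.residual_template(g_u, g_u), np.zeros(20))

    def test_null_prediction_returns_activity(self, rng):
        g_u = rng.random(20)
        np.testing.assert_array_equal(mc.residual_template(g_u, np.zeros(20)), g_u)

    def test_rectification_kills_overshoot(self):
        g_u = np.array([1.0, 0.0, 1.0])
        w_out = np.array([0.5, 1.0, 2.0])
        np.testing.assert_array_equal(mc.residual_template(g_u, w_out), [0.5, 0.0, 0.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mc.residual_template(np.ones(3), np.ones(4))


class TestStateInvariants:
    def test_init_state_nonnegative_and_shaped(self, rng, default_params):
        state = mc.init_state(50, 6, default_params, rng)
        assert state.w_in.shape == (50, 6)
        assert state.w_out.shape == (6, 50)
        assert (state.w_in >= 0).all() and (state.w_out >= 0).all()
        assert not state.used.any()

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError):
            mc.ModelState(np.ones((5, 2)), np.ones((3, 5)), np.zeros(2, dtype=bool))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            mc.ModelState(-np.ones((5, 2)), np.ones((2, 5)), np.zeros(2, dtype=bool))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            mc.ModelParams(kappa_log=0.0).validate()
        with pytest.raises(ValueError):
            mc.ModelParams(lam=-1.0).validate()
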