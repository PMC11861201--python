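"""Spring-equilibrium displacement models, fitting and regression metrics."""

import numpy as np
import pytest

import myoface as mf
from myoface import keypoints as kpmod
from myoface.keypoints import (
    DOUBLE_SYSTEMS,
    MuscleMember,
    SINGLE_SYSTEMS,
    SpringParams,
    _loss_and_grad,
    _pack,
    initial_parameters,
)
from myoface.core import KEYPOINTS, MUSCLES


class TestSingleSystem:
    def test_zero_activation_zero_rest_offset(self):
        p = SpringParams(10, 20, 0.0, 0.05)
        assert mf.smsm_single_displacement(p, 100.0, 0.0) == 0.0

    def test_hand_value_half_activation(self):
        p = SpringParams(10, 20, 0.0, 0.02)
        assert mf.smsm_single_displacement(p, 100.0, 0.5) == \
            pytest.approx(1.6667e-3, rel=1e-4)

    def test_hand_value_full_activation(self):
        p = SpringParams(10, 20, 0.0, 0.02)
        assert mf.smsm_single_displacement(p, 100.0, 1.0) == \
            pytest.approx(4.6154e-3, rel=1e-4)

    def test_monotone_increasing_for_positive_l1(self):
        p = SpringParams(8.0, 15.0, 0.0, 0.7)
        u = np.linspace(0, 1, 101)
        d = mf.smsm_single_displacement(p, 100.0, u)
        assert np.all(np.diff(d) > 0)


class TestDoubleSystem:
    def test_reduces_to_single_when_second_muscle_off(self):
        m1 = MuscleMember(10, 20, 0.0, 0.03, a=1.0, lam=1.0)
        m2 = MuscleMember(5, 7, 0.1, 0.02, a=0.0, lam=1.0)
        u = np.linspace(0, 1, 11)
        d = mf.smsm_double_displacement((m1, m2), 100.0, (u, 0.3 * u))
        ref = mf.smsm_single_displacement(SpringParams(10, 20, 0.0, 0.03),
                                          100.0, u)
        assert np.allclose(d, ref, atol=1e-15)

    def test_mirror_antagonists_cancel(self):
        m1 = MuscleMember(10, 20, 0.0, 0.02, 1.0, 1.0)
        m2 = MuscleMember(10, 20, 0.0, -0.02, 1.0, 1.0)
        u = np.linspace(0, 1, 7)
        assert np.allclose(mf.smsm_double_displacement((m1, m2), 100.0, (u, u)),
                           0.0, atol=1e-15)

    def test_hand_value(self):
        mZ = MuscleMember(10, 20, 0.0, 0.02, 1.0, 1.0)
        mD = MuscleMember(10, 20, 0.0, -0.02, 1.0, 1.0)
        d = mf.smsm_double_displacement((mZ, mD), 100.0, (0.8, 0.2))
        assert d == pytest.approx(2.5714e-3, rel=1e-4)


def _scalar_forward(params, U):
    """Independent scalar re-implementation of the keypoint wiring."""
    T = U.shape[1]
    out = np.zeros((5, T))
    midx = {m: i for i, m in enumerate(MUSCLES)}
    for t in range(T):
        for row, kp in enumerate(KEYPOINTS):
            if kp in SINGLE_SYSTEMS:
                p = params.singles[kp]
                u = U[midx[SINGLE_SYSTEMS[kp]], t]
                g = p.k0 + p.k1 * u
                out[row, t] = g * (p.l0 + p.l1 * u) / (params.KH + g)
            else:
                num = den = 0.0
                for p, mus in zip(params.doubles[kp], DOUBLE_SYSTEMS[kp]):
                    u = U[midx[mus], t]
                    g = p.k0 + p.k1 * u
                    num += p.a * g * (p.l0 + p.l1 * u)
                    den += p.a * p.lam * g
                out[row, t] = num / (params.KH + den)
    return out


class TestForward:
    def test_zero_activation_zero_displacement(self):
        params = mf.default_smsm_parameters()
        assert np.allclose(mf.smsm_forward(params, np.zeros((7, 5))), 0.0)

    def test_matches_independent_scalar_implementation(self, rng):
        params = mf.default_smsm_parameters()
        U = rng.random((7, 20))
        assert np.allclose(mf.smsm_forward(params, U),
                           _scalar_forward(params, U), atol=1e-12)

    def test_wrong_channel_count_rejected(self, rng):
        with pytest.raises(ValueError):
            mf.smsm_forward(mf.default_smsm_parameters(), rng.random((6, 5)))


class TestParameterGuards:
    def test_negative_stiffness_rejected(self):
        p = mf.default_smsm_parameters()
        p.singles["nose"].k0 = -1.0
        with pytest.raises(ValueError, match="stiffness"):
            kpmod.SMSMParameters(p.singles, p.doubles)

    def test_denominator_floor_enforced_over_activation_box(self):
        p = mf.default_smsm_parameters()
        # strongly negative a*lam drives the denominator through zero
        bad = (MuscleMember(10, 20, 0.0, 0.5, a=-10.0, lam=10.0),
               MuscleMember(10, 20, 0.0, 0.5, a=1.0, lam=1.0))
        with pytest.raises(ValueError, match="denominator"):
            kpmod.SMSMParameters(p.singles, {**p.doubles, "mouth_corner": bad})


class TestLinearModels:
    def test_lrm_zero_weights(self, rng):
        assert np.all(mf.lrm_predict(np.zeros((5, 7)), rng.random((7, 9))) == 0)

    def test_lrm_single_entry_selects_channel(self, rng):
        W = np.zeros((5, 7))
        W[0, 0] = 1.0
        U = rng.random((7, 9))
        assert np.allclose(mf.lrm_predict(W, U)[0], U[0])

    def test_lrm_hand_product(self):
        W = np.zeros((5, 7))
        W[0, :2] = 1.0
        U = np.zeros((7, 1))
        U[0, 0], U[1, 0] = 0.2, 0.3
        assert mf.lrm_predict(W, U)[0, 0] == pytest.approx(0.5)

    def test_hybrid_identity_equals_forward(self, rng):
        params = mf.default_smsm_parameters()
        U = rng.random((7, 15))
        assert np.allclose(mf.hybrid_predict(params, np.eye(5), U),
                           mf.smsm_forward(params, U))

    def test_hybrid_zero_weights(self, rng):
        params = mf.default_smsm_parameters()
        assert np.all(mf.hybrid_predict(params, np.zeros((5, 5)),
                                        rng.random((7, 8))) == 0)


class TestGradients:
    @pytest.mark.parametrize("fit_W", [False, True])
    def test_analytic_gradient_matches_finite_differences(self, fit_W):
        rng = np.random.default_rng(3)
        U = rng.random((7, 25))
        Y = 0.05 * rng.standard_normal((5, 25))
        p0 = initial_parameters(rng)
        W0 = np.eye(5) + 0.05 * rng.standard_normal((5, 5)) if fit_W else None
        theta = _pack(p0, W0) + 0.05 * rng.standard_normal(
            kpmod._N_SPRING + (25 if fit_W else 0))
        _, g = _loss_and_grad(theta, U, Y, 100.0, fit_W)
        for i in range(0, len(theta), 3):
            e = np.zeros_like(theta)
            e[i] = 1e-6
            lp, _ = _loss_and_grad(theta + e, U, Y, 100.0, fit_W)
            lm, _ = _loss_and_grad(theta - e, U, Y, 100.0, fit_W)
            num = (lp - lm) / 2e-6
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-10)


def _toy_trials(rng, n_trials=5, T=120):
    W_true = rng.standard_normal((5, 7)) * 0.05
    U = [rng.random((7, T)) for _ in range(n_trials)]
    Y = [W_true @ u for u in U]
    return W_true, U, Y


class TestFitting:
    def test_lrm_closed_form_recovers_true_weights(self, rng):
        W_true, U, Y = _toy_trials(rng)
        fit = mf.fit_model("LRM", U, Y, folds=5, seed=0)
        assert np.allclose(fit.W_lrm, W_true, atol=1e-6)
        assert fit.selected_fold == int(np.argmin(fit.fold_val_losses))

    def test_lrm_adam_loss_curve_nonincreasing_over_500_epoch_spans(self, rng):
        _, U, Y = _toy_trials(rng, n_trials=2, T=80)
        fit = mf.fit_model("LRM", U, Y, epochs=2000, folds=2, seed=0,
                           lrm_method="adam")
        c = fit.loss_curve
        span = 500
        assert np.all(c[span:] <= c[:-span] * (1 + 1e-9) + 1e-15)

    def test_fewer_trials_than_folds_rejected(self, rng):
        _, U, Y = _toy_trials(rng, n_trials=3)
        with pytest.raises(ValueError, match="folds"):
            mf.fit_model("LRM", U, Y, folds=5)

    def test_unknown_model_kind_rejected(self, rng):
        _, U, Y = _toy_trials(rng)
        with pytest.raises(ValueError, match="model kind"):
            mf.fit_model("MLP", U, Y)

    def test_metrics_scale_invariant_under_displacement_rescaling(self, rng):
        W_true, U, Y = _toy_trials(rng)
        alpha = 37.0
        f1 = mf.fit_model("LRM", U, Y, folds=5, seed=0)
        f2 = mf.fit_model("LRM", U, [alpha * y for y in Y], folds=5, seed=0)
        Ute = rng.random((7, 60))
        Yte = W_true @ Ute
        m1 = mf.regression_metrics(Yte, f1.predict(Ute))
        m2 = mf.regression_metrics(alpha * Yte, f2.predict(Ute))
        assert m1["mean_nrmse"] == pytest.approx(m2["mean_nrmse"], abs=1e-10)
        assert m1["mean_r2"] == pytest.approx(m2["mean_r2"], abs=1e-8)


class TestRegressionMetrics:
    def test_perfect_prediction(self, rng):
        Y = rng.random((5, 30))
        m = mf.regression_metrics(Y, Y.copy())
        assert m["mean_r2"] == pytest.approx(100.0)
        assert m["mean_nrmse"] == pytest.approx(0.0)

    def test_mean_predictor_gives_zero_r2(self, rng):
        Y = rng.random((5, 30))
        pred = np.tile(Y.mean(axis=1, keepdims=True), (1, 30))
        assert mf.regression_metrics(Y, pred)["mean_r2"] == pytest.approx(0.0)

    def test_hand_nrmse(self):
        Y = np.tile([[0.0, 1.0, 2.0]], (5, 1))
        P = np.tile([[0.0, 1.0, 3.0]], (5, 1))
        m = mf.regression_metrics(Y, P)
        assert np.sqrt(np.mean((Y[0] - P[0]) ** 2)) == pytest.approx(0.57735,
                                                                     abs=1e-5)
        assert m["mean_nrmse"] == pytest.approx(0.28868, abs=1e-5)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            mf.regression_metrics(np.ones((5, 4)), np.ones((5, 4)))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mf.regression_metrics(rng.random((5, 4)), rng.random((5, 5)))


def _manual_anova(groups):
    """Textbook one-way ANOVA F statistic."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    k, n = len(groups), len(all_x)
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestCompareModels:
    def test_identical_groups_not_significant(self):
        g = np.array([0.1, 0.2, 0.3])
        res = mf.compare_models({"a": g, "b": g.copy(), "c": g.copy()})
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for p in res.tukey_p.values())

    def test_one_group_apart(self):
        res = mf.compare_models({"a": np.zeros(3), "b": np.ones(3),
                                 "c": np.ones(3)})
        assert res.p_value < 1e-6
        assert res.tukey_p[("a", "b")] < 0.05
        assert res.tukey_p[("a", "c")] < 0.05
        p_bc = res.tukey_p[("b", "c")]
        assert np.isnan(p_bc) or p_bc > 0.05

    def test_f_statistic_matches_textbook_formula(self, rng):
        groups = {f"m{i}": rng.random(10) for i in range(3)}
        res = mf.compare_models(groups)
        assert res.f_statistic == pytest.approx(
            _manual_anova(list(groups.values())), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mf.compare_models({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})
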