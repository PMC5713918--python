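import numpy as np
import pytest

from fuzzytrack.clustering import SubtractiveParams
from fuzzytrack.fis import (
    GaussianMF,
    Rule,
    RuleBase,
    build_fcm_fis,
    build_sub_fis,
    firing_strengths,
    fit_consequents,
    infer,
    mf_eval,
    normalize_firing,
)
from fuzzytrack.motion_data import TrainingSet, fit_normalization

from conftest import make_affine_training_set


def make_rule_base(rng, n_rules=3, d=9):
    rules = []
    for _ in range(n_rules):
        premise = tuple(
            GaussianMF(float(c), float(s))
            for c, s in zip(rng.uniform(0, 1, d), rng.uniform(0.05, 0.5, d))
        )
        rules.append(Rule(premise, rng.standard_normal(d), float(rng.standard_normal())))
    return RuleBase(rules, d, "y")


class TestMembership:
    def test_peak_at_center(self):
        assert mf_eval(GaussianMF(0.3, 0.2), 0.3) == 1.0

    def test_one_sigma_value(self):
        assert mf_eval(GaussianMF(0.0, 0.5), 0.5) == pytest.approx(np.exp(-0.5))

    def test_grid_matches_formula(self):
        mf = GaussianMF(0.4, 0.13)
        x = np.linspace(-1, 2, 101)
        np.testing.assert_allclose(
            mf_eval(mf, x), np.exp(-((x - 0.4) ** 2) / (2 * 0.13**2)), atol=1e-15
        )

    def test_rejects_sub_floor_width(self):
        with pytest.raises(ValueError):
            GaussianMF(0.0, 1e-6)


class TestFiring:
    def test_input_at_premise_centers_fires_fully(self, rng):
        rb = make_rule_base(rng, n_rules=2)
        x = np.array([mf.center for mf in rb.rules[0].premise])
        w = firing_strengths(rb, x)
        assert w[0] == pytest.approx(1.0)

    def test_matches_per_dimension_product(self, rng):
        rb = make_rule_base(rng, n_rules=3)
        x = rng.uniform(0, 1, 9)
        w = firing_strengths(rb, x)
        for i, rule in enumerate(rb.rules):
            expected = np.prod([mf_eval(mf, xi) for mf, xi in zip(rule.premise, x)])
            assert w[i] == pytest.approx(expected, rel=1e-12)

    def test_normalization_sums_to_one(self, rng):
        w = rng.uniform(0.1, 2.0, 7)
        wbar = normalize_firing(w)
        assert wbar.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(wbar, w / w.sum())

    def test_zero_sum_guarded(self):
        with pytest.raises(ValueError):
            normalize_firing(np.zeros(3))


class TestInfer:
    def test_single_rule_is_exactly_linear(self, rng):
        rb = make_rule_base(rng, n_rules=1)
        rule = rb.rules[0]
        for _ in range(5):
            x = rng.uniform(-2, 2, 9)
            assert infer(rb, x) == pytest.approx(float(rule.coeffs @ x + rule.intercept))

    def test_identical_consequents_collapse(self, rng):
        base = make_rule_base(rng, n_rules=3)
        coeffs, intercept = base.rules[0].coeffs, base.rules[0].intercept
        rules = [Rule(r.premise, coeffs, intercept) for r in base.rules]
        rb = RuleBase(rules, 9, "y")
        x = rng.uniform(0, 1, 9)
        assert infer(rb, x) == pytest.approx(float(coeffs @ x + intercept))

    def test_matches_sum_of_terms_oracle(self, rng):
        rb = make_rule_base(rng, n_rules=3)
        for _ in range(50):
            x = rng.uniform(0, 1, 9)
            w = firing_strengths(rb, x)
            wbar = w / w.sum()
            expected = sum(
                wb * (r.coeffs @ x + r.intercept) for wb, r in zip(wbar, rb.rules)
            )
            assert infer(rb, x) == pytest.approx(float(expected), abs=1e-12)

    def test_output_bounded_by_rule_outputs(self, rng):
        rb = make_rule_base(rng, n_rules=4)
        for _ in range(20):
            x = rng.uniform(-0.5, 1.5, 9)
            outs = [float(r.coeffs @ x + r.intercept) for r in rb.rules]
            assert min(outs) - 1e-9 <= infer(rb, x) <= max(outs) + 1e-9


class TestFitConsequents:
    def test_affine_data_reproduced_on_training_points(self, rng):
        rb = make_rule_base(rng, n_rules=3)
        X = rng.uniform(0, 1, size=(30, 9))
        a, b = rng.standard_normal(9), 0.7
        y = X @ a + b
        fitted, diag = fit_consequents(rb, X, y)
        np.testing.assert_allclose(fitted.infer_batch(X), y, atol=1e-8)
        assert diag["residual_rmse"] < 1e-8

    def test_single_rule_equals_least_squares_on_noiseless_data(self, rng):
        rb = make_rule_base(rng, n_rules=1)
        X = rng.uniform(0, 1, size=(30, 9))
        a, b = rng.standard_normal(9), -0.4
        y = X @ a + b
        fitted, _ = fit_consequents(rb, X, y)
        np.testing.assert_allclose(fitted.rules[0].coeffs, a, atol=1e-7)
        assert fitted.rules[0].intercept == pytest.approx(b, abs=1e-7)

    def test_single_rule_close_to_ols_under_noise(self, rng):
        rb = make_rule_base(rng, n_rules=1)
        X = rng.uniform(0, 1, size=(200, 9))
        y = X @ rng.standard_normal(9) + 0.5 + 0.05 * rng.standard_normal(200)
        fitted, _ = fit_consequents(rb, X, y)
        B = np.column_stack([X, np.ones(200)])
        theta, *_ = np.linalg.lstsq(B, y, rcond=None)
        pred_ols = B @ theta
        np.testing.assert_allclose(fitted.infer_batch(X), pred_ols, atol=0.02)

    def test_rank_deficient_design_flags_and_stays_finite(self, rng):
        rb = make_rule_base(rng, n_rules=3)
        row = rng.uniform(0, 1, 9)
        X = np.tile(row, (6, 1))
        y = np.full(6, 1.3)
        fitted, diag = fit_consequents(rb, X, y)
        assert diag["rank_deficient"] and diag["underdetermined"]
        assert np.all(np.isfinite([r.intercept for r in fitted.rules]))


class TestBuilders:
    def test_noiseless_linear_coupling_recovered(self, rng):
        train, A, b = make_affine_training_set(rng)
        test_X = rng.uniform(-5, 5, size=(50, 9))
        expected = test_X @ A.T + b
        for builder in (build_sub_fis, build_fcm_fis):
            model = builder(train)
            np.testing.assert_allclose(model.predict(test_X), expected, atol=1e-6)

    def test_rule_count_equals_subtractive_center_count(self, rng):
        train, _, _ = make_affine_training_set(rng, noise=0.5)
        model = build_sub_fis(train)
        from fuzzytrack.clustering import subtractive_cluster

        norm = fit_normalization(train)
        Xn = norm.normalize_inputs(train.X)
        Yn = norm.normalize_outputs(train.Y)
        for j, rb in enumerate(model.rule_bases):
            joint = np.column_stack([Xn, Yn[:, j]])
            assert rb.n_rules == subtractive_cluster(joint).n_clusters

    def test_single_cluster_data_yields_one_linear_rule(self, rng):
        # one dense mass plus a tiny satellite: the satellite's potential
        # falls below the reject ratio, so clustering returns one center
        a = rng.uniform(-2, 2, 9)
        b = a + rng.uniform(0.5, 1.0, 9)
        X = np.vstack([np.tile(a, (25, 1)), np.tile(b, (2, 1))])
        X += 1e-6 * rng.standard_normal(X.shape)  # keep timestamps/rows distinct
        Y = X @ rng.uniform(-1, 1, size=(3, 9)).T + 0.05 * rng.standard_normal((27, 3))
        train = TrainingSet(X, Y, np.arange(27, dtype=float))
        model = build_fcm_fis(train)
        assert all(rb.n_rules == 1 for rb in model.rule_bases)
        # a single first-order rule is a globally affine predictor
        p, q = rng.uniform(-2, 2, 9), rng.uniform(-2, 2, 9)
        mid = model.predict((p + q)[None] / 2)
        np.testing.assert_allclose(
            mid, (model.predict(p[None]) + model.predict(q[None])) / 2, atol=1e-9
        )

    def test_two_regime_coupling_beats_global_linear_fit(self, rng):
        # internal response kinks at s = 0: slope 1 below, 4 above
        n = 60
        X = np.tile(rng.uniform(-1, 1, size=(n, 1)), (1, 9))
        s = X[:, 0]
        y = np.where(s < 0, s, 4 * s)
        Y = np.column_stack([y, y, y])
        train = TrainingSet(X, Y, np.arange(n, dtype=float))
        model = build_fcm_fis(train)
        test_s = np.linspace(-0.9, 0.9, 80)
        test_X = np.tile(test_s[:, None], (1, 9))
        truth = np.where(test_s < 0, test_s, 4 * test_s)
        fcm_rmse = np.sqrt(np.mean((model.predict(test_X)[:, 0] - truth) ** 2))
        B = np.column_stack([X, np.ones(n)])
        theta, *_ = np.linalg.lstsq(B, Y[:, 0], rcond=None)
        lin_rmse = np.sqrt(
            np.mean((np.column_stack([test_X, np.ones(80)]) @ theta - truth) ** 2)
        )
        assert fcm_rmse < lin_rmse

    def test_prediction_invariant_to_training_row_permutation(self, rng):
        train, _, _ = make_affine_training_set(rng, noise=0.4)
        perm = rng.permutation(train.n_points)
        # pairs stay together; only row order (and hence timestamps) changes
        shuffled = TrainingSet(
            train.X[perm], train.Y[perm], np.arange(train.n_points, dtype=float)
        )
        probe = rng.uniform(-5, 5, size=(20, 9))
        m1 = build_sub_fis(train)
        m2 = build_sub_fis(shuffled)
        np.testing.assert_allclose(m1.predict(probe), m2.predict(probe), atol=1e-9)

    def test_input_unit_rescaling_leaves_mm_predictions_unchanged(self, rng):
        train, _, _ = make_affine_training_set(rng, noise=0.3)
        scaled = TrainingSet(
            train.X * np.array([1000.0] + [1.0] * 8), train.Y, train.timestamps
        )
        probe = rng.uniform(-5, 5, size=(20, 9))
        scaled_probe = probe * np.array([1000.0] + [1.0] * 8)
        m1 = build_sub_fis(train)
        m2 = build_sub_fis(scaled)
        np.testing.assert_allclose(m1.predict(probe), m2.predict(scaled_probe), atol=1e-9)
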