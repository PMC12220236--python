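"""Differential-penalty ridge refit (soft and hard EAML)."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from eaml.refit import (EAMLVariant, exclusion_order, fit_penalized_logistic,
                        hard_eaml, predict, soft_eaml)
from eaml.rules import FittedRuleModel, Rule, RuleCondition, \
    RuleFitHyperparams, build_rule_matrix


def _binary_design(n=500, p=3, seed=0, beta=(1.5, -1.0, 0.8), b0=-0.4):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < 0.4).astype(float)
    eta = b0 + X @ np.asarray(beta)
    y = (rng.random(n) < expit(eta)).astype(int)
    return X, y


def _assessments(ids, deltas, sds=None):
    sds = sds if sds is not None else [0.5] * len(ids)
    deltas = np.asarray(deltas, dtype=float)
    return pd.DataFrame({
        "model_rank": np.arange(1, len(ids) + 1, dtype=float),
        "expert_rank": np.arange(1, len(ids) + 1, dtype=float) - deltas,
        "expert_sd": sds, "delta_rank": deltas,
        "delta_rank_over_sd": deltas / np.asarray(sds)},
        index=pd.Index(ids, name="rule_id"))


def _model_from(X, y, ids):
    rules = [Rule(i, (RuleCondition(f"f{j}", "numeric_gt", 0.5),))
             for j, i in enumerate(ids)]
    return FittedRuleModel(
        all_rules=rules, selected_rules=rules, intercept=0.0,
        coefficients={i: 1.0 for i in ids},
        hyperparams=RuleFitHyperparams())


class TestPenalizedFit:
    def test_uniform_factors_match_sklearn_ridge(self):
        X, y = _binary_design()
        lam = 0.01
        b0, b = fit_penalized_logistic(X, y, lam)
        # sklearn l2 objective: C * sum loss + 0.5 ||w||^2  =>
        # ours * n/...: C = 1 / (2 n lam)
        clf = LogisticRegression(C=1.0 / (2 * len(y) * lam), solver="lbfgs",
                                 max_iter=20000, tol=1e-12).fit(X, y)
        assert b0 == pytest.approx(clf.intercept_[0], abs=1e-6)
        np.testing.assert_allclose(b, clf.coef_[0], atol=1e-6)

    def test_zero_lambda_matches_unpenalized_mle(self):
        X, y = _binary_design(seed=2)
        b0, b = fit_penalized_logistic(X, y, 0.0)
        fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert b0 == pytest.approx(fit.params[0], abs=1e-4)
        np.testing.assert_allclose(b, fit.params[1:], atol=1e-4)

    def test_matches_generic_optimizer_oracle(self):
        X, y = _binary_design(n=300, seed=4)
        lam, pf = 0.05, np.array([0.2, 1.0, 2.5])
        b0, b = fit_penalized_logistic(X, y, lam, pf)

        def oracle_obj(w):  # independent restatement of the objective
            eta = w[0] + X @ w[1:]
            ll = -(y * np.log(expit(eta)) +
                   (1 - y) * np.log(1 - expit(eta))).mean()
            return ll + lam * np.sum(pf * w[1:] ** 2)

        res = minimize(oracle_obj, np.zeros(4), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        np.testing.assert_allclose(np.r_[b0, b], res.x, atol=1e-4)

    def test_zero_factor_coordinate_is_unpenalized(self):
        X, y = _binary_design(seed=5)
        b0_big, b_big = fit_penalized_logistic(X, y, 5.0,
                                               np.array([0.0, 1.0, 1.0]))
        # heavily penalized coords nearly vanish; the free one solves the
        # single-column unpenalized fit with them at zero
        assert abs(b_big[1]) < 0.01 and abs(b_big[2]) < 0.01
        ref = sm.Logit(y, sm.add_constant(X[:, [0]])).fit(disp=0)
        assert b_big[0] == pytest.approx(ref.params[1], abs=5e-3)

    def test_huge_factor_limit_converges_to_exclusion(self):
        # unnormalized factors: as one factor grows unboundedly at fixed
        # lambda, the fit converges to the model excluding that rule
        X, y = _binary_design(seed=7)
        lam = 0.01
        b0, b = fit_penalized_logistic(X, y, lam, np.array([1e6, 1.0, 1.0]))
        assert abs(b[0]) < 1e-5
        b0_x, b_x = fit_penalized_logistic(X[:, 1:], y, lam)
        assert b0 == pytest.approx(b0_x, abs=1e-5)
        np.testing.assert_allclose(b[1:], b_x, atol=1e-5)

    def test_deviance_monotone_when_penalties_upweighted(self):
        # factors componentwise >= uniform can only worsen training fit
        X, y = _binary_design(seed=5)

        def dev(b0, b):
            p = expit(b0 + X @ b)
            return -2 * (y * np.log(p) + (1 - y) * np.log(1 - p)).sum()

        lam = 0.05
        d_uni = dev(*fit_penalized_logistic(X, y, lam))
        d_up = dev(*fit_penalized_logistic(X, y, lam,
                                           np.array([4.0, 2.0, 1.5])))
        assert d_up >= d_uni - 1e-9

    def test_identity_link_matches_ridge_closed_form(self):
        from sklearn.linear_model import Ridge

        from eaml.refit import fit_penalized_linear
        X, y = _binary_design(seed=12)
        lam = 0.05
        b0, b = fit_penalized_linear(X, y, lam)
        # sklearn Ridge: ||y - Xw - c||^2 + alpha ||w||^2 => alpha = n lam
        r = Ridge(alpha=len(y) * lam).fit(X, y)
        np.testing.assert_allclose(b, r.coef_, atol=1e-8)
        assert b0 == pytest.approx(r.intercept_, abs=1e-8)

    def test_negative_factors_rejected(self):
        X, y = _binary_design()
        with pytest.raises(ValueError):
            fit_penalized_logistic(X, y, 0.1, np.array([-1.0, 1, 1]))


class TestSoft:
    def test_equal_discordance_reduces_to_uniform_ridge(self):
        X, y = _binary_design(seed=1)
        ids = ["a", "b", "c"]
        M = pd.DataFrame(X, columns=ids)
        model = _model_from(X, y, ids)
        lam = 0.02
        soft = soft_eaml(M, y, _assessments(ids, [4, -4, 4]), model,
                         ridge_lambda=lam)
        b0_u, b_u = fit_penalized_logistic(X, y, lam)
        assert soft.intercept == pytest.approx(b0_u, abs=1e-6)
        np.testing.assert_allclose([soft.coefficients[i] for i in ids], b_u,
                                   atol=1e-6)
        assert np.mean(list(soft.penalty_factors.values())) == \
            pytest.approx(1.0)

    def test_discrepant_rule_shrinks_others_grow(self):
        X, y = _binary_design(seed=3)
        ids = ["a", "b", "c"]
        M = pd.DataFrame(X, columns=ids)
        model = _model_from(X, y, ids)
        lam = 0.05
        uniform = soft_eaml(M, y, _assessments(ids, [1, 1, 1]), model,
                            ridge_lambda=lam)
        skewed = soft_eaml(M, y, _assessments(ids, [30, 1, 1]), model,
                           ridge_lambda=lam)
        assert abs(skewed.coefficients["a"]) < \
            abs(uniform.coefficients["a"])
        assert abs(skewed.coefficients["b"]) >= \
            abs(uniform.coefficients["b"]) - 1e-9
        assert abs(skewed.coefficients["c"]) >= \
            abs(uniform.coefficients["c"]) - 1e-9

    def test_zero_lambda_ignores_penalty_factors(self):
        X, y = _binary_design(seed=6)
        ids = ["a", "b", "c"]
        M = pd.DataFrame(X, columns=ids)
        model = _model_from(X, y, ids)
        s1 = soft_eaml(M, y, _assessments(ids, [30, 1, 1]), model,
                       ridge_lambda=0.0)
        fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            [s1.coefficients[i] for i in ids], fit.params[1:], atol=1e-4)

    def test_extreme_discordance_shifts_penalty_budget(self):
        # mean-1 normalization hands an extreme |delta/SD| rule nearly the
        # entire penalty budget (factor -> R), shrinking it well below its
        # uniform-ridge value while freeing the others almost entirely
        X, y = _binary_design(seed=7)
        ids = ["a", "b", "c"]
        M = pd.DataFrame(X, columns=ids)
        model = _model_from(X, y, ids)
        lam = 0.01
        a = _assessments(ids, [1e6, 1, 1])
        soft = soft_eaml(M, y, a, model, ridge_lambda=lam)
        hard = hard_eaml(M, y, a, model, k=1, ridge_lambda=lam)
        assert soft.penalty_factors["a"] == pytest.approx(3.0, abs=1e-4)
        _, b_u = fit_penalized_logistic(X, y, lam)
        assert abs(soft.coefficients["a"]) < abs(b_u[0])
        # wrapper consistency with the core penalized fit
        pf = np.array([soft.penalty_factors[i] for i in ids])
        b0_d, b_d = fit_penalized_logistic(X, y, lam, pf)
        np.testing.assert_allclose(
            [soft.coefficients[i] for i in ids], b_d, atol=1e-8)
        assert "a" not in hard.coefficients

    def test_missing_assessment_fails(self):
        X, y = _binary_design()
        ids = ["a", "b", "c"]
        M = pd.DataFrame(X, columns=ids)
        model = _model_from(X, y, ids)
        with pytest.raises(ValueError, match="c"):
            soft_eaml(M, y, _assessments(["a", "b"], [1, 1]), model,
                      ridge_lambda=0.1)



class TestHard:
    def test_exclusion_order_by_abs_delta_over_sd_then_delta_then_id(self):
        a = _assessments(["a", "b", "c", "d"], [2, -8, 8, 2],
                         [0.5, 0.5, 0.5, 0.5])
        a.loc["c", "delta_rank"] = 8.0
        order = exclusion_order(a)
        assert order[:2] in (["b", "c"], ["c", "b"])
        assert order[2:] == ["a", "d"]  # tie on both -> rule_id order

    def test_k0_is_uniform_ridge_baseline(self):
        X, y = _binary_design(seed=9)
        ids = ["a", "b", "c"]
        M = pd.DataFrame(X, columns=ids)
        model = _model_from(X, y, ids)
        h0 = hard_eaml(M, y, _assessments(ids, [5, 1, -2]), model, k=0,
                       ridge_lambda=0.02)
        b0_u, b_u = fit_penalized_logistic(X, y, 0.02)
        np.testing.assert_allclose([h0.coefficients[i] for i in ids], b_u,
                                   atol=1e-8)
        assert len(h0.included_rules) == 3

    def test_k_removes_most_discrepant_rules(self):
        X, y = _binary_design(seed=10)
        ids = ["a", "b", "c"]
        M = pd.DataFrame(X, columns=ids)
        model = _model_from(X, y, ids)
        h = hard_eaml(M, y, _assessments(ids, [9, -1, 5]), model, k=2,
                      ridge_lambda=0.02)
        assert [r.rule_id for r in h.included_rules] == ["b"]
        assert sorted(h.provenance["excluded_rule_ids"]) == ["a", "c"]

    def test_k_too_large_fails(self):
        X, y = _binary_design()
        ids = ["a", "b", "c"]
        M = pd.DataFrame(X, columns=ids)
        model = _model_from(X, y, ids)
        with pytest.raises(ValueError, match="k=3"):
            hard_eaml(M, y, _assessments(ids, [1, 1, 1]), model, k=3)

    def test_single_rule_model_predicts_two_values(self):
        X, y = _binary_design(seed=11)
        ids = ["a", "b", "c"]
        M = pd.DataFrame(X, columns=ids)
        model = _model_from(X, y, ids)
        h = hard_eaml(M, y, _assessments(ids, [9, -1, 5]), model, k=2,
                      ridge_lambda=0.01)
        table = pd.DataFrame({"f1": [0.0, 1.0, 0.0, 1.0]})
        scores = predict(h, table)
        assert len(np.unique(np.round(scores, 12))) == 2


class TestStructure:
    def test_refit_preserves_rule_definitions(self, small_model,
                                              small_cohort,
                                              small_assessments):
        M = build_rule_matrix(small_model.selected_rules,
                              small_cohort.train)
        y = small_cohort.train.df["outcome"]
        soft = soft_eaml(M, y, small_assessments, small_model,
                         ridge_lambda=1e-3)
        hard = hard_eaml(M, y, small_assessments, small_model, k=3,
                         ridge_lambda=1e-3)
        sel = {r.rule_id: r.key() for r in small_model.selected_rules}
        assert [r.rule_id for r in soft.included_rules] == list(sel)
        for m in (soft, hard):
            for r in m.included_rules:
                assert r.key() == sel[r.rule_id]
        assert len(hard.included_rules) == len(sel) - 3

    def test_variant_validation(self):
        with pytest.raises(ValueError):
            EAMLVariant("medium")
        with pytest.raises(ValueError):
            EAMLVariant("hard")
        assert EAMLVariant("hard", 3).name == "hard-3"

    def test_predict_closed_forms(self):
        r = Rule("a", (RuleCondition("f", "numeric_gt", 0.0),))
        m = FittedRuleModel([r], [r], intercept=-1.0,
                            coefficients={"a": 2.0},
                            hyperparams=RuleFitHyperparams())
        t = pd.DataFrame({"f": [-1.0, 1.0]})
        np.testing.assert_allclose(predict(m, t),
                                   [expit(-1.0), expit(1.0)])
        empty = FittedRuleModel([], [], intercept=0.3, coefficients={},
                                hyperparams=RuleFitHyperparams())
        np.testing.assert_allclose(predict(empty, t), expit(0.3))
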