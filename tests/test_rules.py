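"""Rule extraction, evaluation, activation matrix and L1 selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from eaml.rules import (HyperparamGrid, Rule, RuleCondition,
                        RuleFitHyperparams, build_rule_matrix, evaluate_rule,
                        extract_rules, fit_boosted_trees,
                        fit_lasso_selection, fit_rulefit, predict_scores,
                        tune_hyperparameters)


def leaf(value=0.0):
    return {"leaf_value": value}


def split(feature_idx, threshold, left, right):
    return {"split_feature": feature_idx, "threshold": threshold,
            "left_child": left, "right_child": right}


def dump(features, *trees):
    return {"feature_names": list(features),
            "tree_info": [{"tree_structure": t} for t in trees]}


class TestExtraction:
    def test_depth1_tree_yields_two_complementary_rules(self):
        d = dump(["x"], split(0, 5.0, leaf(), leaf()))
        rules = extract_rules(None, model_dump=d)
        assert [r.render() for r in rules] == ["x ≤ 5", "x > 5"]

    def test_depth2_paths_enumerated_and_nested_conditions_collapse(self):
        # root: x<=5; left child splits y<=2; right child splits x<=8.
        # Paths below the root (6 nodes): x<=5; x<=5&y<=2; x<=5&y>2;
        # x>5; x>5&x<=8 (interval); x>8 (tighter lower bound).
        d = dump(["x", "y"], split(0, 5.0,
                                   split(1, 2.0, leaf(), leaf()),
                                   split(0, 8.0, leaf(), leaf())))
        rules = extract_rules(None, model_dump=d)
        assert [r.render() for r in rules] == [
            "x ≤ 5", "x ≤ 5 & y ≤ 2", "x ≤ 5 & y > 2",
            "x > 5", "x > 5 & x ≤ 8", "x > 8"]

    def test_duplicate_paths_across_trees_deduplicate(self):
        t = split(0, 5.0, leaf(), leaf())
        d = dump(["x"], t, t)
        assert len(extract_rules(None, model_dump=d)) == 2

    def test_leaves_only_drops_internal_nodes(self):
        d = dump(["x", "y"], split(0, 5.0, split(1, 2.0, leaf(), leaf()),
                                   leaf()))
        rules = extract_rules(None, model_dump=d, leaves_only=True)
        assert [r.render() for r in rules] == [
            "x ≤ 5 & y ≤ 2", "x ≤ 5 & y > 2", "x > 5"]


class TestEvaluate:
    rule = Rule("r", (RuleCondition("age", "numeric_le", 10),
                      RuleCondition("rr", "numeric_le", 30)))

    def test_all_conditions_hold(self):
        assert evaluate_rule(self.rule, {"age": 5, "rr": 20}) == 1

    def test_one_condition_fails(self):
        assert evaluate_rule(self.rule, {"age": 12, "rr": 20}) == 0

    def test_empty_conjunction_always_fires(self):
        assert evaluate_rule(Rule("e"), {"anything": 1}) == 1

    def test_missing_feature_is_an_error_not_zero(self):
        with pytest.raises(KeyError, match="age"):
            evaluate_rule(self.rule, {"rr": 20})

    def test_categorical_membership(self):
        r = Rule("c", (RuleCondition("sbt", "categorical_in",
                                     levels=frozenset({"Passed"})),))
        assert evaluate_rule(r, {"sbt": "Passed"}) == 1
        assert evaluate_rule(r, {"sbt": "Failed"}) == 0


class TestMatrix:
    def test_single_rule_column(self):
        df = pd.DataFrame({"x": [3.0, 1.0, 4.0]})
        r = Rule("r", (RuleCondition("x", "numeric_le", 2),))
        M = build_rule_matrix([r], df)
        assert M["r"].tolist() == [0, 1, 0]

    def test_matrix_equals_bruteforce_and_means_equal_support(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 40)
            df = pd.DataFrame({
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.choice(["u", "v", "w"], size=n)})
            rules = []
            for j in range(rng.integers(1, 6)):
                conds = [RuleCondition("a", "numeric_le",
                                       float(rng.normal()))]
                if rng.random() < 0.5:
                    conds.append(RuleCondition("b", "numeric_gt",
                                               float(rng.normal())))
                if rng.random() < 0.5:
                    conds.append(RuleCondition(
                        "c", "categorical_in",
                        levels=frozenset(rng.choice(["u", "v", "w"],
                                                    size=2))))
                rules.append(Rule(f"r{j}", tuple(conds)))
            M = build_rule_matrix(rules, df)
            for r in rules:
                brute = [evaluate_rule(r, df.iloc[i]) for i in range(n)]
                assert M[r.rule_id].tolist() == brute
                assert M[r.rule_id].mean() == np.mean(brute)

    def test_depth1_rule_columns_partition_the_sample(self):
        df = pd.DataFrame({"x": np.linspace(-3, 3, 50)})
        rules = extract_rules(None, model_dump=dump(
            ["x"], split(0, 0.0, leaf(), leaf())))
        M = build_rule_matrix(rules, df)
        assert (M.sum(axis=1) == 1).all()

    def test_missing_feature_reports_rule_context(self):
        df = pd.DataFrame({"x": [1.0]})
        r = Rule("bad", (RuleCondition("zz", "numeric_le", 0),))
        with pytest.raises(KeyError, match="bad"):
            build_rule_matrix([r], df)


def _toy_matrix(n=400, p=4, seed=3):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < 0.4).astype(float)
    beta = np.array([2.0, -1.5, 1.0, 0.0])
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta - 0.3)))).astype(int)
    M = pd.DataFrame(X, columns=[f"r{j}" for j in range(p)])
    return M, y


class TestLasso:
    def test_huge_lambda_selects_nothing_and_predicts_base_rate(self):
        M, y = _toy_matrix()
        model = fit_lasso_selection(M, y, lasso_lambda=10.0)
        assert model.selected_rules == []
        rate = y.mean()
        pred = 1 / (1 + np.exp(-model.intercept))
        assert pred == pytest.approx(rate, abs=0.01)

    def test_zero_lambda_matches_irls_oracle(self):
        M, y = _toy_matrix()
        model = fit_lasso_selection(M, y, lasso_lambda=0.0)
        sm_fit = sm.Logit(y, sm.add_constant(M.to_numpy())).fit(disp=0)
        assert model.intercept == pytest.approx(sm_fit.params[0], abs=1e-4)
        coefs = [model.coefficients.get(c, 0.0) for c in M.columns]
        np.testing.assert_allclose(coefs, sm_fit.params[1:], atol=1e-4)

    def test_selected_count_monotone_in_lambda(self):
        M, y = _toy_matrix()
        counts = [len(fit_lasso_selection(M, y, lasso_lambda=lam)
                      .selected_rules)
                  for lam in (1e-4, 1e-3, 1e-2, 1e-1, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_duplicate_column_leaves_predictions_unchanged(self):
        M, y = _toy_matrix()
        lam = 1e-3
        base = fit_lasso_selection(M, y, lasso_lambda=lam)
        M2 = M.copy()
        M2["r0_dup"] = M["r0"]
        dup = fit_lasso_selection(M2, y, lasso_lambda=lam)
        b = np.array([base.coefficients.get(c, 0.0) for c in M.columns])
        d = np.array([dup.coefficients.get(c, 0.0) for c in M2.columns])
        p_base = M.to_numpy() @ b + base.intercept
        p_dup = M2.to_numpy() @ d + dup.intercept
        np.testing.assert_allclose(p_base, p_dup, atol=5e-3)

    def test_all_zero_column_warned_and_unselected(self):
        M, y = _toy_matrix()
        M["dead"] = 0
        with pytest.warns(UserWarning, match="dead"):
            model = fit_lasso_selection(M, y, lasso_lambda=1e-3)
        assert "dead" not in model.coefficients


def _sep_frame(n=300, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-2, 2, size=n)
    return pd.DataFrame({"intubation_id": np.arange(n), "x": x,
                         "outcome": (x > 0).astype(int)})


class TestBoosting:
    def test_perfect_separation_recovers_threshold(self):
        hp = RuleFitHyperparams(num_leaves=2, n_trees=1,
                                min_child_samples=5)
        booster, enc = fit_boosted_trees(_sep_frame(), hp)
        rules = extract_rules(booster, enc)
        thr = rules[0].conditions[0].threshold
        assert abs(thr) < 0.15

    def test_single_class_outcome_fails(self):
        df = _sep_frame()
        df["outcome"] = 1
        with pytest.raises(ValueError, match="single class"):
            fit_boosted_trees(df, RuleFitHyperparams())

    def test_fixed_seed_reproduces_ensemble_and_fit(self):
        df = _sep_frame(seed=5)
        hp = RuleFitHyperparams(num_leaves=2, n_trees=8, lasso_lambda=1e-3,
                                min_child_samples=5)
        m1 = fit_rulefit(df, hp, seed=42)
        m2 = fit_rulefit(df, hp, seed=42)
        assert m1.to_json() == m2.to_json()


def _xor_frame(n=800, seed=1):
    """Signal only expressible at depth 2: outcome follows agreement of
    the signs of x and y."""
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=n), rng.normal(size=n)
    agree = (x > 0) == (y > 0)
    p = np.where(agree, 0.88, 0.12)
    return pd.DataFrame({"intubation_id": np.arange(n), "x": x, "y": y,
                         "outcome": (rng.random(n) < p).astype(int)})


class TestTuning:
    def test_grid_of_one_returns_that_point(self):
        grid = HyperparamGrid(learning_rates=[0.3], num_leaves=[2],
                              lambdas=[1e-3], n_folds=2)
        hp = tune_hyperparameters(_sep_frame(), grid)
        assert (hp.learning_rate, hp.num_leaves, hp.lasso_lambda) == \
            (0.3, 2, 1e-3)

    def test_interaction_signal_selects_expressive_leaf_count(self):
        df = _xor_frame()
        grid = HyperparamGrid(learning_rates=[0.2], num_leaves=[2, 4],
                              lambdas=[1e-3], n_folds=3, n_trees=16, seed=0)
        hp = tune_hyperparameters(df, grid)
        assert hp.num_leaves == 4

    def test_tuning_is_deterministic_given_seed(self):
        df = _sep_frame()
        grid = HyperparamGrid(learning_rates=[0.1, 0.3], num_leaves=[2],
                              lambdas=[1e-3, 1e-2], n_folds=2, n_trees=4,
                              seed=9)
        assert tune_hyperparameters(df, grid) == \
            tune_hyperparameters(df, grid)


class TestStudyScale:
    def test_candidate_count_near_study_order_and_selection_sparser(
            self, small_model):
        # study analogue: a strict subset of ~O(100) candidates selected
        assert 20 <= len(small_model.all_rules) <= 200
        assert 0 < len(small_model.selected_rules) < \
            len(small_model.all_rules)
        assert all(v != 0 for v in small_model.coefficients.values())

    def test_model_serialization_roundtrip(self, small_model,
                                           small_cohort):
        from eaml.rules import FittedRuleModel
        clone = FittedRuleModel.from_json(small_model.to_json())
        np.testing.assert_allclose(
            predict_scores(clone, small_cohort.test),
            predict_scores(small_model, small_cohort.test))
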