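"""Rule-ensemble (RuleFit-style) baseline model.

Pipeline: gradient-boosted shallow trees -> conjunctive rules (one per
root-to-node path, internal nodes included) -> Boolean rule-activation
matrix -> L1-penalized logistic regression to select a sparse rule subset.
Hyperparameters (boosting learning rate, leaf count, lasso lambda) are
chosen by cross-validation on the training split.

Categorical features are one-hot encoded before boosting; splits on dummy
columns are translated back to ``categorical_in`` conditions on the
original feature so that extracted rules read naturally ("sbt in
{Passed, Failed}" rather than "sbt=Passed > 0.5").
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "RuleCondition",
    "Rule",
    "RuleFitHyperparams",
    "HyperparamGrid",
    "FittedRuleModel",
    "fit_boosted_trees",
    "extract_rules",
    "evaluate_rule",
    "build_rule_matrix",
    "fit_lasso_selection",
    "tune_hyperparameters",
    "fit_rulefit",
]

NUMERIC_LE = "numeric_le"
NUMERIC_GT = "numeric_gt"
CATEGORICAL_IN = "categorical_in"


def _as_frame(table) -> pd.DataFrame:
    """Accept a CohortTable or a plain DataFrame."""
    return table.df if hasattr(table, "df") else table


@dataclass(frozen=True)
class RuleCondition:
    """One atomic condition of a conjunctive rule.

    ``kind`` is ``numeric_le`` (feature <= threshold), ``numeric_gt``
    (feature > threshold) or ``categorical_in`` (feature level in
    ``levels``).
    """

    feature: str
    kind: str
    threshold: float | None = None
    levels: frozenset[str] | None = None

    def __post_init__(self):
        if self.kind in (NUMERIC_LE, NUMERIC_GT):
            if self.threshold is None or not np.isfinite(self.threshold):
                raise ValueError(f"finite threshold required for {self.kind}")
        elif self.kind == CATEGORICAL_IN:
            if not self.levels:
                raise ValueError("categorical_in requires a non-empty level set")
            object.__setattr__(self, "levels", frozenset(self.levels))
        else:
            raise ValueError(f"unknown condition kind: {self.kind!r}")

    def holds(self, value) -> bool:
        if self.kind == NUMERIC_LE:
            return value <= self.threshold
        if self.kind == NUMERIC_GT:
            return value > self.threshold
        return value in self.levels

    def render(self) -> str:
        if self.kind == NUMERIC_LE:
            return f"{self.feature} ≤ {self.threshold:.4g}"
        if self.kind == NUMERIC_GT:
            return f"{self.feature} > {self.threshold:.4g}"
        lv = ", ".join(sorted(self.levels))
        return f"{self.feature} ∈ {{{lv}}}"

    def _key(self):
        if self.kind == CATEGORICAL_IN:
            return (self.feature, self.kind, tuple(sorted(self.levels)))
        return (self.feature, self.kind, float(self.threshold))


@dataclass
class Rule:
    """A conjunction of atomic conditions; fires (value 1) for a record when
    every condition holds.  The empty conjunction fires everywhere."""

    rule_id: str
    conditions: tuple[RuleCondition, ...] = ()
    support_train: float | None = None

    def __post_init__(self):
        # deduplicate identical conditions, keep first-seen order
        seen, out = set(), []
        for c in self.conditions:
            if c._key() not in seen:
                seen.add(c._key())
                out.append(c)
        self.conditions = tuple(out)

    def key(self):
        return tuple(sorted(c._key() for c in self.conditions))

    def features(self) -> list[str]:
        seen = []
        for c in self.conditions:
            if c.feature not in seen:
                seen.append(c.feature)
        return seen

    def render(self) -> str:
        if not self.conditions:
            return "(always)"
        return " & ".join(c.render() for c in self.conditions)

    def to_dict(self) -> dict:
        conds = []
        for c in self.conditions:
            d = {"feature": c.feature, "kind": c.kind}
            if c.kind == CATEGORICAL_IN:
                d["levels"] = sorted(c.levels)
            else:
                d["threshold"] = c.threshold
            conds.append(d)
        return {"rule_id": self.rule_id, "conditions": conds,
                "support_train": self.support_train}

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        conds = []
        for c in d["conditions"]:
            if c["kind"] == CATEGORICAL_IN:
                conds.append(RuleCondition(c["feature"], c["kind"],
                                           levels=frozenset(c["levels"])))
            else:
                conds.append(RuleCondition(c["feature"], c["kind"],
                                           threshold=c["threshold"]))
        return cls(d["rule_id"], tuple(conds), d.get("support_train"))


def evaluate_rule(rule: Rule, record: Mapping) -> int:
    """1 iff every condition of ``rule`` holds for ``record``.

    Raises ``KeyError`` when the record lacks a referenced feature — a
    missing feature is an error, never a silent 0.
    """
    for cond in rule.conditions:
        if cond.feature not in record:
            raise KeyError(
                f"rule {rule.rule_id!r} references feature {cond.feature!r} "
                "absent from record")
        if not cond.holds(record[cond.feature]):
            return 0
    return 1


def build_rule_matrix(rules: Sequence[Rule], table) -> pd.DataFrame:
    """Boolean activation matrix: rows = records, columns = rules.

    Entry (i, j) is 1 iff every condition of rule j holds for record i.
    Column means equal the rules' supports on ``table``.
    """
    if len(rules) == 0:
        raise ValueError("rules must be non-empty")
    df = _as_frame(table)
    cols = {}
    for rule in rules:
        mask = np.ones(len(df), dtype=bool)
        for cond in rule.conditions:
            if cond.feature not in df.columns:
                raise KeyError(
                    f"rule {rule.rule_id!r} references feature "
                    f"{cond.feature!r} absent from table")
            col = df[cond.feature]
            if cond.kind == NUMERIC_LE:
                mask &= (col.to_numpy(dtype=float) <= cond.threshold)
            elif cond.kind == NUMERIC_GT:
                mask &= (col.to_numpy(dtype=float) > cond.threshold)
            else:
                mask &= col.isin(cond.levels).to_numpy()
        cols[rule.rule_id] = mask.astype(np.int8)
    return pd.DataFrame(cols, index=df.index)


# --------------------------------------------------------------------------
# boosting stage
# --------------------------------------------------------------------------

@dataclass
class RuleFitHyperparams:
    learning_rate: float = 0.1
    num_leaves: int = 4
    n_trees: int = 32
    lasso_lambda: float | None = None  # None -> choose by CV
    min_child_samples: int = 20

    def to_dict(self):
        return {"learning_rate": self.learning_rate,
                "num_leaves": self.num_leaves, "n_trees": self.n_trees,
                "lasso_lambda": self.lasso_lambda,
                "min_child_samples": self.min_child_samples}


@dataclass
class HyperparamGrid:
    learning_rates: Sequence[float] = (0.05, 0.1)
    num_leaves: Sequence[int] = (3, 4)
    lambdas: Sequence[float] = (1e-4, 1e-3, 1e-2)
    n_folds: int = 3
    n_trees: int = 32
    seed: int = 0

    def __post_init__(self):
        if not (self.learning_rates and self.num_leaves and self.lambdas):
            raise ValueError("grid lists must be non-empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


class FeatureEncoding:
    """One-hot encoding of categorical features for the boosting stage.

    Keeps the map from dummy column name back to (feature, level) so tree
    splits on dummies can be rendered as categorical_in conditions.
    """

    def __init__(self, feature_names: Sequence[str],
                 categorical_levels: Mapping[str, Sequence[str]]):
        self.feature_names = list(feature_names)
        self.categorical_levels = {k: list(v)
                                   for k, v in categorical_levels.items()}
        self.columns: list[str] = []
        self.dummy_map: dict[str, tuple[str, str]] = {}
        for name in self.feature_names:
            if name in self.categorical_levels:
                for level in self.categorical_levels[name]:
                    col = f"{name}={level}"
                    self.columns.append(col)
                    self.dummy_map[col] = (name, level)
            else:
                self.columns.append(name)

    def transform(self, table) -> pd.DataFrame:
        df = _as_frame(table)
        out = {}
        for col in self.columns:
            if col in self.dummy_map:
                name, level = self.dummy_map[col]
                out[col] = (df[name] == level).astype(float).to_numpy()
            else:
                out[col] = df[col].to_numpy(dtype=float)
        return pd.DataFrame(out, index=df.index)


def _encoding_for(table) -> FeatureEncoding:
    df = _as_frame(table)
    feats = getattr(table, "feature_names", None)
    if feats is None:
        reserved = {"intubation_id", "window_index", "window_end_time",
                    "split", "outcome"}
        feats = [c for c in df.columns if c not in reserved]
    cat = getattr(table, "categorical_levels", None)
    if cat is None:
        cat = {c: sorted(df[c].dropna().unique())
               for c in feats if df[c].dtype == object}
    return FeatureEncoding(feats, cat)


def fit_boosted_trees(train, hyperparams: RuleFitHyperparams, seed: int = 0,
                      encoding: FeatureEncoding | None = None):
    """Fit the shallow gradient-boosted tree ensemble on the training split.

    Returns ``(booster, encoding)``.  Fails explicitly on a single-class
    outcome.
    """
    df = _as_frame(train)
    y = df["outcome"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome has a single class; cannot boost")
    enc = encoding or _encoding_for(train)
    X = enc.transform(train)
    model = LGBMClassifier(
        n_estimators=hyperparams.n_trees,
        num_leaves=hyperparams.num_leaves,
        learning_rate=hyperparams.learning_rate,
        min_child_samples=hyperparams.min_child_samples,
        random_state=seed,
        deterministic=True,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(X, y)
    return model.booster_, enc


# --------------------------------------------------------------------------
# rule extraction
# --------------------------------------------------------------------------

def _merge_conditions(path: Sequence[RuleCondition]) -> tuple[RuleCondition, ...]:
    """Merge a path's conditions per feature: numeric conditions intersect to
    the tightest interval; categorical level sets intersect."""
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    cats: dict[str, frozenset] = {}
    order: list[str] = []
    for c in path:
        if c.feature not in order:
            order.append(c.feature)
        if c.kind == NUMERIC_LE:
            hi[c.feature] = min(hi.get(c.feature, np.inf), c.threshold)
        elif c.kind == NUMERIC_GT:
            lo[c.feature] = max(lo.get(c.feature, -np.inf), c.threshold)
        else:
            prev = cats.get(c.feature)
            cats[c.feature] = c.levels if prev is None else prev & c.levels
    merged = []
    for f in order:
        if f in cats:
            merged.append(RuleCondition(f, CATEGORICAL_IN, levels=cats[f]))
            continue
        if f in lo and np.isfinite(lo[f]):
            merged.append(RuleCondition(f, NUMERIC_GT, threshold=lo[f]))
        if f in hi and np.isfinite(hi[f]):
            merged.append(RuleCondition(f, NUMERIC_LE, threshold=hi[f]))
    return tuple(merged)


def _split_conditions(node: dict, dummy_map: Mapping[str, tuple[str, str]],
                      feature_names: Sequence[str],
                      levels: Mapping[str, Sequence[str]]):
    """Left/right child conditions for a lightgbm split node."""
    col = feature_names[node["split_feature"]]
    thr = float(node["threshold"])
    if col in dummy_map:
        feat, level = dummy_map[col]
        universe = frozenset(levels[feat])
        # dummy <= thr (thr in (0,1)) means the level is NOT taken
        left = RuleCondition(feat, CATEGORICAL_IN, levels=universe - {level})
        right = RuleCondition(feat, CATEGORICAL_IN, levels=frozenset({level}))
        return left, right
    return (RuleCondition(col, NUMERIC_LE, threshold=thr),
            RuleCondition(col, NUMERIC_GT, threshold=thr))


def extract_rules(booster, encoding: FeatureEncoding | None = None,
                  leaves_only: bool = False,
                  model_dump: dict | None = None) -> list[Rule]:
    """Extract conjunctive rules from a boosted ensemble.

    One rule per root-to-node path for every node strictly below a root
    (internal and leaf nodes alike, unless ``leaves_only``).  Conditions on
    the same feature along a path are merged to the tightest interval;
    exact duplicate rules are removed; ordering is deterministic (tree
    index, then depth-first emission order).

    Accepts either a fitted booster or a pre-dumped model dict (the
    lightgbm ``dump_model`` schema) for testing on hand-written trees.
    """
    dump = model_dump if model_dump is not None else booster.dump_model()
    feature_names = dump["feature_names"]
    dummy_map = encoding.dummy_map if encoding is not None else {}
    levels = encoding.categorical_levels if encoding is not None else {}

    raw: list[tuple[tuple, Rule]] = []
    seen: set = set()
    rules: list[Rule] = []

    def visit(node: dict, path: list[RuleCondition], is_root: bool):
        if not is_root:
            conds = _merge_conditions(path)
            if not (leaves_only and "split_feature" in node):
                key = tuple(sorted(c._key() for c in conds))
                if key not in seen:
                    seen.add(key)
                    rules.append(Rule(rule_id="", conditions=conds))
        if "split_feature" in node:
            left_c, right_c = _split_conditions(node, dummy_map,
                                                feature_names, levels)
            visit(node["left_child"], path + [left_c], False)
            visit(node["right_child"], path + [right_c], False)

    for tree in dump["tree_info"]:
        root = tree["tree_structure"]
        if "split_feature" not in root:  # stump with no split
            continue
        visit(root, [], True)

    for i, rule in enumerate(rules):
        rule.rule_id = f"R{i + 1:03d}"
    return rules


# --------------------------------------------------------------------------
# L1 selection
# --------------------------------------------------------------------------

@dataclass
class FittedRuleModel:
    """RuleFit baseline: the candidate rules, the L1-selected subset and the
    sparse logistic coefficients over the selected rules."""

    all_rules: list[Rule]
    selected_rules: list[Rule]
    intercept: float
    coefficients: dict[str, float]
    hyperparams: RuleFitHyperparams
    cv_metadata: dict = field(default_factory=dict)

    @property
    def rules(self) -> list[Rule]:
        return self.selected_rules

    def predict(self, table) -> np.ndarray:
        return predict_scores(self, table)

    def to_json(self) -> str:
        return json.dumps({
            "all_rules": [r.to_dict() for r in self.all_rules],
            "selected_rules": [r.to_dict() for r in self.selected_rules],
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "hyperparams": self.hyperparams.to_dict(),
            "cv_metadata": self.cv_metadata,
        }, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "FittedRuleModel":
        d = json.loads(s)
        return cls(
            all_rules=[Rule.from_dict(r) for r in d["all_rules"]],
            selected_rules=[Rule.from_dict(r) for r in d["selected_rules"]],
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            hyperparams=RuleFitHyperparams(**d["hyperparams"]),
            cv_metadata=d.get("cv_metadata", {}),
        )


def predict_scores(model, table) -> np.ndarray:
    """Per-record probability: logistic(intercept + sum coef_j * rule_j)."""
    rules = model.rules
    if not rules:
        df = _as_frame(table)
        return np.full(len(df), expit(model.intercept))
    M = build_rule_matrix(rules, table)
    beta = np.array([model.coefficients[r.rule_id] for r in rules])
    return expit(model.intercept + M.to_numpy(dtype=float) @ beta)


def _lasso_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                    seed: int = 0, max_iter: int = 20000,
                    tol: float = 1e-9) -> tuple[float, np.ndarray]:
    """L1-penalized logistic fit; objective (1/n) sum loss + lam * ||beta||_1
    (intercept unpenalized).  lam = 0 gives the unpenalized fit.

    Solved by FISTA (accelerated proximal gradient with function-value
    restart): soft-thresholding yields exact zero coefficients and the
    solver is deterministic, including in the heavy-shrinkage regime.
    """
    n = len(y)
    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000,
                                 tol=1e-10)
        clf.fit(X, y)
        return float(clf.intercept_[0]), clf.coef_[0].copy()

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xa = np.column_stack([np.ones(n), X])
    # Lipschitz constant of the gradient: ||Xa||_2^2 / (4n), spectral norm
    # by power iteration
    v = np.ones(Xa.shape[1]) / np.sqrt(Xa.shape[1])
    for _ in range(100):
        v_new = Xa.T @ (Xa @ v)
        v_norm = np.linalg.norm(v_new)
        v = v_new / v_norm
    L = v_norm / (4 * n) * 1.01
    step = 1.0 / L

    def smooth_grad(w):
        z = Xa @ w
        return Xa.T @ (expit(z) - y) / n

    def objective(w):
        z = Xa @ w
        s = (2 * y - 1) * z
        return np.logaddexp(0.0, -s).mean() + lam * np.abs(w[1:]).sum()

    w = np.zeros(Xa.shape[1])
    z_acc = w.copy()
    t = 1.0
    f_prev = objective(w)
    for _ in range(max_iter):
        g = smooth_grad(z_acc)
        w_new = z_acc - step * g
        w_new[1:] = np.sign(w_new[1:]) * np.maximum(
            np.abs(w_new[1:]) - step * lam, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z_acc = w_new + (t - 1) / t_new * (w_new - w)
        f_new = objective(w_new)
        if f_new > f_prev:  # restart momentum on non-descent
            z_acc, t_new = w_new.copy(), 1.0
        if np.max(np.abs(w_new - w)) < tol and abs(f_prev - f_new) < tol:
            w, t, f_prev = w_new, t_new, f_new
            break
        w, t, f_prev = w_new, t_new, f_new
    beta = w[1:]
    beta[np.abs(beta) < 1e-12] = 0.0
    return float(w[0]), beta


def fit_lasso_selection(matrix: pd.DataFrame, outcomes, lasso_lambda=None,
                        lambdas: Sequence[float] = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2),
                        n_folds: int = 3, seed: int = 0,
                        all_rules: Sequence[Rule] | None = None,
                        hyperparams: RuleFitHyperparams | None = None,
                        ) -> FittedRuleModel:
    """L1-penalized logistic selection over the Boolean rule matrix.

    Rules whose coefficient shrinks exactly to zero are dropped; the
    intercept is never penalized; Boolean columns are not standardized
    (rules share the {0,1} scale).  When ``lasso_lambda`` is None the
    penalty is chosen by ``n_folds``-fold CV maximizing AUC (ties toward
    the larger, sparser lambda).
    """
    y = np.asarray(outcomes, dtype=int)
    if len(matrix) != len(y):
        raise ValueError("matrix rows must match outcome length")
    X = matrix.to_numpy(dtype=float)
    zero_cols = [c for c, s in zip(matrix.columns, X.sum(axis=0)) if s == 0]
    if zero_cols:
        warnings.warn(f"all-zero rule columns (never fire): {zero_cols}")

    cv_meta: dict = {}
    if lasso_lambda is None:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(y))
        folds = np.array_split(idx, n_folds)
        mean_auc = {}
        for lam in lambdas:
            aucs = []
            for k in range(n_folds):
                val = folds[k]
                tr = np.concatenate([folds[j] for j in range(n_folds) if j != k])
                if len(np.unique(y[tr])) < 2 or len(np.unique(y[val])) < 2:
                    continue
                b0, b = _lasso_logistic(X[tr], y[tr], lam, seed)
                aucs.append(roc_auc_score(y[val], X[val] @ b + b0))
            mean_auc[lam] = float(np.mean(aucs)) if aucs else np.nan
        # ties toward larger lambda (sparser model)
        lasso_lambda = max(sorted(lambdas, reverse=True),
                           key=lambda l: (mean_auc[l],))
        cv_meta = {"lambda_cv_auc": {str(k): v for k, v in mean_auc.items()},
                   "chosen_lambda": lasso_lambda}

    b0, beta = _lasso_logistic(X, y, lasso_lambda, seed)
    coef = dict(zip(matrix.columns, beta))
    rules_by_id = {r.rule_id: r for r in (all_rules or [])}
    selected = []
    for rid in matrix.columns:
        if coef[rid] != 0.0:
            selected.append(rules_by_id.get(rid, Rule(rule_id=rid)))
    hp = hyperparams or RuleFitHyperparams()
    hp.lasso_lambda = lasso_lambda
    return FittedRuleModel(
        all_rules=list(all_rules) if all_rules else
        [rules_by_id.get(c, Rule(rule_id=c)) for c in matrix.columns],
        selected_rules=selected,
        intercept=b0,
        coefficients={rid: coef[rid] for rid in coef if coef[rid] != 0.0},
        hyperparams=hp,
        cv_metadata=cv_meta,
    )


def fit_rulefit(train, hyperparams: RuleFitHyperparams | None = None,
                seed: int = 0, leaves_only: bool = False,
                lambdas: Sequence[float] = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2),
                n_folds: int = 3) -> FittedRuleModel:
    """Boost -> extract rules -> Boolean matrix -> L1 selection."""
    hp = hyperparams or RuleFitHyperparams()
    booster, enc = fit_boosted_trees(train, hp, seed=seed)
    rules = extract_rules(booster, enc, leaves_only=leaves_only)
    if not rules:
        raise ValueError("boosting produced no rules; increase n_trees or "
                         "loosen min_child_samples")
    df = _as_frame(train)
    M = build_rule_matrix(rules, train)
    for r in rules:
        r.support_train = float(M[r.rule_id].mean())
    model = fit_lasso_selection(
        M, df["outcome"], lasso_lambda=hp.lasso_lambda, lambdas=lambdas,
        n_folds=n_folds, seed=seed, all_rules=rules, hyperparams=hp)
    return model


def _cv_auc_for_point(train, hp: RuleFitHyperparams, lam: float,
                      n_folds: int, seed: int) -> float:
    """Mean out-of-fold AUC of the full rulefit pipeline at one grid point.
    Folds are cut on intubations so windows from one intubation never
    straddle a fold."""
    df = _as_frame(train)
    ids = df["intubation_id"].unique()
    rng = np.random.default_rng(seed)
    ids = rng.permutation(ids)
    folds = np.array_split(ids, n_folds)
    aucs = []
    for k in range(n_folds):
        val_mask = df["intubation_id"].isin(folds[k]).to_numpy()
        tr_df, val_df = df[~val_mask], df[val_mask]
        if tr_df["outcome"].nunique() < 2 or val_df["outcome"].nunique() < 2:
            continue
        hp_k = RuleFitHyperparams(hp.learning_rate, hp.num_leaves, hp.n_trees,
                                  lam, hp.min_child_samples)
        try:
            model = fit_rulefit(tr_df, hp_k, seed=seed)
        except ValueError:
            continue
        aucs.append(roc_auc_score(val_df["outcome"],
                                  predict_scores(model, val_df)))
    return float(np.mean(aucs)) if aucs else np.nan


def tune_hyperparameters(train, grid: HyperparamGrid) -> RuleFitHyperparams:
    """Grid point maximizing mean CV AUC; ties broken toward smaller
    num_leaves, then smaller learning rate, then larger lambda."""
    points = list(itertools.product(grid.learning_rates, grid.num_leaves,
                                    grid.lambdas))
    if len(points) == 1:
        lr, nl, lam = points[0]
        return RuleFitHyperparams(lr, nl, grid.n_trees, lam)
    scored = []
    for lr, nl, lam in points:
        hp = RuleFitHyperparams(lr, nl, grid.n_trees, lam)
        auc = _cv_auc_for_point(train, hp, lam, grid.n_folds, grid.seed)
        scored.append(((lr, nl, lam), auc))
    best = max(scored, key=lambda t: (np.nan_to_num(t[1], nan=-1.0),
                                      -t[0][1], -t[0][0], t[0][2]))
    lr, nl, lam = best[0]
    return RuleFitHyperparams(lr, nl, grid.n_trees, lam)
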