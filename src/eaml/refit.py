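"""Discordance-guided re-regularization (the EAML refit).

The selected rules and their Boolean activation matrix are frozen from the
RuleFit stage; only coefficients (and, for hard variants, rule inclusion)
change.  Two variants:

* soft — ridge logistic refit with per-rule penalty factors
  p_j = |delta_rank_over_sd_j| normalized to mean 1 (glmnet-style
  ``penalty.factor``), so rules the experts disagree with most are shrunk
  hardest; p_j = 0 leaves a coefficient unpenalized.
* hard-k — drop the k rules with largest |delta_rank_over_sd| (ties:
  larger |delta_rank|, then rule_id), then a uniform ridge refit.

The penalized objective is

    (1/n) sum_i logloss_i  +  lambda * sum_j p_j * beta_j^2

minimized directly (intercept unpenalized).  Scaling column j by
1/sqrt(p_j) and running a uniform ridge fit is algebraically equivalent
for p_j > 0; the direct form also covers p_j = 0 exactly.  lambda is
re-tuned by CV per variant unless fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .rules import FittedRuleModel, Rule, predict_scores

__all__ = [
    "EAMLVariant",
    "fit_penalized_linear",
    "EAMLModel",
    "fit_penalized_logistic",
    "soft_eaml",
    "hard_eaml",
    "predict",
    "DEFAULT_K_GRID",
]

DEFAULT_K_GRID = (1, 3, 5, 7, 10, 11)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-5, -1, 9))


@dataclass(frozen=True)
class EAMLVariant:
    kind: str                    # "soft" or "hard"
    k_excluded: int | None = None

    def __post_init__(self):
        if self.kind not in ("soft", "hard"):
            raise ValueError("variant kind must be 'soft' or 'hard'")
        if self.kind == "hard" and (self.k_excluded is None
                                    or self.k_excluded < 0):
            raise ValueError("hard variant needs k_excluded >= 0")

    @property
    def name(self) -> str:
        return "soft" if self.kind == "soft" else f"hard-{self.k_excluded}"


@dataclass
class EAMLModel:
    """Re-regularized rule model: same rules (a subset, for hard variants),
    new coefficients."""

    variant: EAMLVariant
    included_rules: list[Rule]
    intercept: float
    coefficients: dict[str, float]
    ridge_lambda: float
    penalty_factors: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def rules(self) -> list[Rule]:
        return self.included_rules

    def predict(self, table) -> np.ndarray:
        return predict_scores(self, table)

    def to_dict(self) -> dict:
        return {
            "variant": {"kind": self.variant.kind,
                        "k_excluded": self.variant.k_excluded},
            "included_rules": [r.to_dict() for r in self.included_rules],
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "ridge_lambda": self.ridge_lambda,
            "penalty_factors": self.penalty_factors,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EAMLModel":
        return cls(EAMLVariant(**d["variant"]),
                   [Rule.from_dict(r) for r in d["included_rules"]],
                   d["intercept"], d["coefficients"], d["ridge_lambda"],
                   d.get("penalty_factors", {}), d.get("provenance", {}))


def fit_penalized_linear(X: np.ndarray, y: np.ndarray, lam: float,
                         penalty_factors: np.ndarray | None = None
                         ) -> tuple[float, np.ndarray]:
    """Identity-link variant: minimize (1/n)||y - b0 - X b||^2 +
    lam * sum_j p_j b_j^2, intercept unpenalized (closed form)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(
        penalty_factors, dtype=float)
    if (pf < 0).any():
        raise ValueError("penalty factors must be >= 0")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    A = Xc.T @ Xc / n + lam * np.diag(pf)
    beta = np.linalg.solve(A, Xc.T @ yc / n)
    b0 = float(y.mean() - X.mean(axis=0) @ beta)
    return b0, beta


def fit_penalized_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                           penalty_factors: np.ndarray | None = None,
                           tol: float = 1e-12) -> tuple[float, np.ndarray]:
    """Minimize (1/n) logistic loss + lam * sum_j p_j beta_j^2.

    Intercept unpenalized; p defaults to uniform 1.  Returns
    (intercept, coefficients)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(
        penalty_factors, dtype=float)
    if (pf < 0).any():
        raise ValueError("penalty factors must be >= 0")

    def objective(w):
        b0, b = w[0], w[1:]
        z = b0 + X @ b
        # log(1 + exp(-(2y-1) z)) computed stably
        s = (2 * y - 1) * z
        loss = np.logaddexp(0.0, -s).mean()
        grad_z = (expit(z) - y) / n
        g0 = grad_z.sum()
        gb = X.T @ grad_z + 2 * lam * pf * b
        pen = lam * float(pf @ (b * b))
        return loss + pen, np.concatenate([[g0], gb])

    res = minimize(objective, np.zeros(p + 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": tol, "gtol": 1e-10})
    return float(res.x[0]), res.x[1:].copy()


def _fitter(link: str):
    if link == "logistic":
        return lambda X, y, lam, pf=None: fit_penalized_logistic(
            X, y, lam, pf, tol=1e-9)
    if link == "identity":
        return fit_penalized_linear
    raise ValueError("link must be 'logistic' or 'identity'")


def _cv_lambda(X, y, penalty_factors, lambdas, n_folds, seed,
               link: str = "logistic") -> float:
    fit = _fitter(link)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, n_folds)
    best, best_auc = None, -np.inf
    for lam in sorted(lambdas, reverse=True):  # ties -> more shrinkage
        aucs = []
        for k in range(n_folds):
            val = folds[k]
            tr = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[val])) < 2:
                continue
            b0, b = fit(X[tr], y[tr], lam, penalty_factors)
            aucs.append(roc_auc_score(y[val], X[val] @ b + b0))
        if aucs and np.mean(aucs) > best_auc:
            best_auc, best = float(np.mean(aucs)), lam
    if best is None:
        raise ValueError("cross-validation failed on every fold")
    return best


def _matrix_for(matrix: pd.DataFrame, rules: Sequence[Rule]):
    ids = [r.rule_id for r in rules]
    missing = [i for i in ids if i not in matrix.columns]
    if missing:
        raise ValueError(f"activation matrix lacks columns: {missing}")
    return matrix[ids].to_numpy(dtype=float), ids


def soft_eaml(matrix: pd.DataFrame, outcomes, assessments: pd.DataFrame,
              model: FittedRuleModel, ridge_lambda: float | None = None,
              lambdas=DEFAULT_LAMBDA_GRID, n_folds: int = 3,
              seed: int = 0, link: str = "logistic") -> EAMLModel:
    """Soft EAML: differential-shrinkage ridge refit of the selected rules.

    Penalty factor for rule j is |delta_rank_over_sd_j| normalized to mean
    1 over the selected rules (all-zero discordance degenerates to uniform
    ridge).  Requires an assessment row for every selected rule.
    """
    y = np.asarray(outcomes, dtype=int)
    rules = model.selected_rules
    missing = [r.rule_id for r in rules if r.rule_id not in assessments.index]
    if missing:
        raise ValueError(f"no assessment for rules: {missing}")
    X, ids = _matrix_for(matrix, rules)
    raw = np.abs(assessments.loc[ids, "delta_rank_over_sd"]
                 .to_numpy(dtype=float))
    pf = raw / raw.mean() if raw.mean() > 0 else np.ones(len(ids))
    lam = ridge_lambda
    if lam is None:
        lam = _cv_lambda(X, y, pf, lambdas, n_folds, seed, link)
    if link == "logistic":
        b0, b = fit_penalized_logistic(X, y, lam, pf)
    else:
        b0, b = _fitter(link)(X, y, lam, pf)
    return EAMLModel(
        EAMLVariant("soft"), list(rules), b0, dict(zip(ids, b)), lam,
        penalty_factors=dict(zip(ids, pf)),
        provenance={"source": "rulefit", "n_selected": len(ids)})


def exclusion_order(assessments: pd.DataFrame) -> list[str]:
    """Rule ids sorted most-discrepant first: descending |delta_rank/SD|,
    ties by descending |delta_rank|, then rule_id."""
    a = assessments
    order = sorted(
        a.index,
        key=lambda rid: (-abs(float(a.loc[rid, "delta_rank_over_sd"])),
                         -abs(float(a.loc[rid, "delta_rank"])), str(rid)))
    return list(order)


def hard_eaml(matrix: pd.DataFrame, outcomes, assessments: pd.DataFrame,
              model: FittedRuleModel, k: int,
              ridge_lambda: float | None = None, lambdas=DEFAULT_LAMBDA_GRID,
              n_folds: int = 3, seed: int = 0,
              link: str = "logistic") -> EAMLModel:
    """Hard EAML: exclude the k most discrepant rules, uniform ridge refit
    of the remainder."""
    rules = model.selected_rules
    if k >= len(rules):
        raise ValueError(f"k={k} must be < number of selected rules "
                         f"({len(rules)})")
    missing = [r.rule_id for r in rules if r.rule_id not in assessments.index]
    if missing:
        raise ValueError(f"no assessment for rules: {missing}")
    sel_ids = {r.rule_id for r in rules}
    drop = set(
        [rid for rid in exclusion_order(assessments.loc[list(sel_ids)])][:k])
    kept = [r for r in rules if r.rule_id not in drop]
    y = np.asarray(outcomes, dtype=int)
    X, ids = _matrix_for(matrix, kept)
    lam = ridge_lambda
    if lam is None:
        lam = _cv_lambda(X, y, None, lambdas, n_folds, seed, link)
    if link == "logistic":
        b0, b = fit_penalized_logistic(X, y, lam)
    else:
        b0, b = _fitter(link)(X, y, lam)
    return EAMLModel(
        EAMLVariant("hard", k), kept, b0, dict(zip(ids, b)), lam,
        provenance={"source": "rulefit", "excluded_rule_ids": sorted(drop)})


def predict(model, table) -> np.ndarray:
    """Per-record probability under a FittedRuleModel or EAMLModel."""
    return predict_scores(model, table)


def models_to_json(models: dict[str, EAMLModel]) -> str:
    return json.dumps({k: m.to_dict() for k, m in models.items()}, indent=1)


def models_from_json(s: str) -> dict[str, EAMLModel]:
    return {k: EAMLModel.from_dict(v) for k, v in json.loads(s).items()}
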