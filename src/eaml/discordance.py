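"""Model-vs-expert rank discordance.

Both the model and the expert panel rank the selected rules in order of
increasing chance of the positive outcome: the model by each rule's
empirical risk in the training set (subgroup outcome rate), the experts by
decreasing mean Likert response (1 = much higher chance).  Rank 1 is the
lowest chance of success.  Per rule,

    delta_rank         = model_rank - expert_rank
    delta_rank_over_sd = delta_rank / expert_sd

so unanimous panels (small SD) amplify a given rank disagreement —
the penalization is strongest where experts agree most.  Negative values
mean the model rated the subgroup less likely to succeed than the experts
did.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata

from .rules import Rule, build_rule_matrix

__all__ = [
    "empirical_risk",
    "empirical_risks",
    "rank_by_model",
    "rank_by_experts",
    "compute_discordance",
    "concordance_summary",
    "ConcordanceSummary",
    "assessment_table",
]

SD_FLOOR_FALLBACK = 0.1


def empirical_risk(rule: Rule, train) -> float:
    """Outcome rate among training records for which the rule fires."""
    df = train.df if hasattr(train, "df") else train
    mask = build_rule_matrix([rule], df)[rule.rule_id].to_numpy(dtype=bool)
    if not mask.any():
        raise ValueError(f"rule {rule.rule_id!r} has zero training support")
    return float(df.loc[mask, "outcome"].mean())


def empirical_risks(rules, train) -> dict[str, float]:
    df = train.df if hasattr(train, "df") else train
    M = build_rule_matrix(rules, df)
    y = df["outcome"].to_numpy(dtype=float)
    out = {}
    for r in rules:
        fires = M[r.rule_id].to_numpy(dtype=bool)
        if not fires.any():
            raise ValueError(f"rule {r.rule_id!r} has zero training support")
        out[r.rule_id] = float(y[fires].mean())
    return out


def _ascending_ranks(values: dict[str, float]) -> dict[str, float]:
    ids = list(values)
    ranks = rankdata([values[i] for i in ids], method="average")
    return dict(zip(ids, ranks.astype(float)))


def rank_by_model(risks: dict[str, float]) -> dict[str, float]:
    """Ascending ranks on empirical risk (1 = lowest chance of success);
    ties get average fractional ranks."""
    if len(risks) < 2:
        raise ValueError("need at least two rules to rank")
    return _ascending_ranks(risks)


def rank_by_experts(aggregated: pd.DataFrame) -> dict[str, float]:
    """Ascending ranks on chance of success from expert means.

    The Likert scale runs 1 = much higher ... 5 = much lower, so chance of
    success *decreases* with the mean response: rank ascending on the
    negated mean.  Ties get average fractional ranks.
    """
    if len(aggregated) < 2:
        raise ValueError("need at least two rules to rank")
    means = {rid: -float(m) for rid, m in aggregated["mean"].items()}
    return _ascending_ranks(means)


def compute_discordance(model_ranks: dict[str, float],
                        expert_ranks: dict[str, float],
                        expert_sds: dict[str, float],
                        sd_floor: float | None = None) -> pd.DataFrame:
    """Per-rule delta rank and delta rank / expert SD.

    A unanimous panel has SD 0, which would make the ratio infinite; SDs
    are floored at the smallest positive SD observed across rules
    (fallback 0.1 when every SD is zero), with a warning.
    Returns a DataFrame indexed by rule_id with columns model_rank,
    expert_rank, expert_sd, delta_rank, delta_rank_over_sd.
    """
    if set(model_ranks) != set(expert_ranks) or set(model_ranks) != set(expert_sds):
        raise ValueError("model ranks, expert ranks and SDs must cover the "
                         "same rule ids")
    ids = list(model_ranks)
    sds = np.array([expert_sds[i] for i in ids], dtype=float)
    if sd_floor is None:
        pos = sds[sds > 0]
        sd_floor = float(pos.min()) if len(pos) else SD_FLOOR_FALLBACK
    if (sds <= 0).any():
        warnings.warn(f"{int((sds <= 0).sum())} rule(s) with zero expert SD; "
                      f"flooring at {sd_floor}")
    eff_sd = np.maximum(sds, sd_floor)
    mr = np.array([model_ranks[i] for i in ids])
    er = np.array([expert_ranks[i] for i in ids])
    delta = mr - er
    return pd.DataFrame({
        "model_rank": mr, "expert_rank": er, "expert_sd": sds,
        "delta_rank": delta, "delta_rank_over_sd": delta / eff_sd,
    }, index=pd.Index(ids, name="rule_id"))


@dataclass
class ConcordanceSummary:
    r_squared: float | None  # None when either variable is constant
    scatter: pd.DataFrame    # rule_id, empirical_risk, expert_mean


def concordance_summary(assessments: pd.DataFrame) -> ConcordanceSummary:
    """OLS R^2 of mean expert response on empirical risk, plus the scatter
    table behind it.  Requires columns empirical_risk and expert_mean."""
    if len(assessments) < 3:
        raise ValueError("need at least three rules for a concordance fit")
    x = assessments["empirical_risk"].to_numpy(dtype=float)
    y = assessments["expert_mean"].to_numpy(dtype=float)
    scatter = assessments.reset_index()[["rule_id", "empirical_risk",
                                         "expert_mean"]]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConcordanceSummary(None, scatter)
    res = linregress(x, y)
    return ConcordanceSummary(float(res.rvalue ** 2), scatter)


def assessment_table(rules, train, aggregated: pd.DataFrame,
                     sd_floor: float | None = None) -> pd.DataFrame:
    """Full per-rule assessment: empirical risk, both ranks, expert mean
    and SD, delta rank and delta rank/SD (Table-2-style layout)."""
    risks = empirical_risks(rules, train)
    mrank = rank_by_model(risks)
    erank = rank_by_experts(aggregated)
    sds = {rid: float(s) for rid, s in aggregated["sd"].items()}
    out = compute_discordance(mrank, erank, sds, sd_floor=sd_floor)
    out.insert(0, "empirical_risk", [risks[i] for i in out.index])
    out.insert(3, "expert_mean",
               [float(aggregated.loc[i, "mean"]) for i in out.index])
    out["rule_text"] = [r.render() for r in rules]
    return out
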