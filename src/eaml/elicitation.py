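"""Expert survey rendering, response ingestion and aggregation.

Each selected rule becomes one survey item comparing the rule's subgroup
with the full training sample: numeric variables show median (min, max),
categorical variables show the mode and all levels present, for both
groups.  Experts answer on a 5-point scale (1 = much higher chance of the
outcome ... 5 = much lower).  Responses are aggregated per rule to a mean
and sample SD, optionally restricted to a role/experience subset (e.g.
attending physicians only, as a sensitivity analysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rules import Rule, build_rule_matrix
from .synthetic import LIKERT_LABELS

__all__ = [
    "SubgroupSummary",
    "SurveyForm",
    "summarize_subgroup",
    "render_survey",
    "ingest_responses",
    "aggregate_responses",
    "QUESTION_STEM",
]

QUESTION_STEM = ("Do patients in the subgroup have a higher or lower chance "
                 "of successful extubation 12 hours from now compared with "
                 "patients in the population?")

RESPONSE_COLUMNS = ["expert_id", "role", "experience_band", "rule_id",
                    "response"]


@dataclass
class SubgroupSummary:
    """Per-variable comparison of a rule's subgroup vs the full training
    sample, restricted to the variables the rule references."""

    rule_id: str
    rule_text: str
    subgroup_n: int
    population_n: int
    numeric: dict[str, dict] = field(default_factory=dict)
    # name -> {"subgroup": (median, min, max), "population": (...)}
    categorical: dict[str, dict] = field(default_factory=dict)
    # name -> {"subgroup": (mode, levels), "population": (mode, levels)}

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id, "rule_text": self.rule_text,
            "subgroup_n": self.subgroup_n, "population_n": self.population_n,
            "numeric": self.numeric, "categorical": self.categorical,
        }


def _num_summary(s: pd.Series) -> tuple[float, float, float]:
    return (float(s.median()), float(s.min()), float(s.max()))


def _cat_summary(s: pd.Series) -> tuple[str, list[str]]:
    mode = s.mode().iloc[0]
    return (str(mode), sorted(str(v) for v in s.unique()))


def summarize_subgroup(rule: Rule, train) -> SubgroupSummary:
    """Summaries of the variables referenced by ``rule`` for its firing
    subgroup and the full training sample."""
    df = train.df if hasattr(train, "df") else train
    mask = build_rule_matrix([rule], df)[rule.rule_id].to_numpy(dtype=bool)
    if not mask.any():
        raise ValueError(f"rule {rule.rule_id!r} fires for no training record")
    sub = df[mask]
    out = SubgroupSummary(rule.rule_id, rule.render(), int(mask.sum()),
                          len(df))
    for name in rule.features():
        col = df[name]
        if col.dtype == object:
            out.categorical[name] = {"subgroup": _cat_summary(sub[name]),
                                     "population": _cat_summary(col)}
        else:
            out.numeric[name] = {"subgroup": _num_summary(sub[name]),
                                 "population": _num_summary(col)}
    return out


@dataclass
class SurveyForm:
    """Ordered survey items plus the anchor labels; the item order is
    randomized once per form under a recorded seed."""

    items: list[SubgroupSummary]
    seed: int
    stem: str = QUESTION_STEM
    scale: dict = field(default_factory=lambda: dict(LIKERT_LABELS))

    @property
    def rule_ids(self) -> list[str]:
        return [it.rule_id for it in self.items]

    def to_json(self) -> str:
        return json.dumps({
            "stem": self.stem, "seed": self.seed,
            "scale": {str(k): v for k, v in self.scale.items()},
            "items": [it.to_dict() for it in self.items],
        }, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "SurveyForm":
        d = json.loads(s)
        items = []
        for it in d["items"]:
            items.append(SubgroupSummary(
                it["rule_id"], it["rule_text"], it["subgroup_n"],
                it["population_n"], it["numeric"], it["categorical"]))
        return cls(items, d["seed"], d["stem"],
                   {int(k): v for k, v in d["scale"].items()})

    def to_markdown(self) -> str:
        lines = ["# Expert survey", ""]
        scale = "; ".join(f"{k} = {v}" for k, v in sorted(self.scale.items()))
        for i, it in enumerate(self.items, 1):
            lines += [f"## Item {i} ({it.rule_id})", "",
                      f"Subgroup rule: `{it.rule_text}` "
                      f"(n = {it.subgroup_n} of {it.population_n} windows)",
                      "",
                      "| Variable | Subgroup | Population |",
                      "|---|---|---|"]
            for name, v in it.numeric.items():
                s, p = v["subgroup"], v["population"]
                lines.append(
                    f"| {name} | {s[0]:.1f} ({s[1]:.1f}, {s[2]:.1f}) "
                    f"| {p[0]:.1f} ({p[1]:.1f}, {p[2]:.1f}) |")
            for name, v in it.categorical.items():
                s, p = v["subgroup"], v["population"]
                lines.append(f"| {name} | {s[0]} ({', '.join(s[1])}) "
                             f"| {p[0]} ({', '.join(p[1])}) |")
            lines += ["", self.stem, "", f"Scale: {scale}", ""]
        return "\n".join(lines)


def render_survey(model, summaries: Sequence[SubgroupSummary] | None = None,
                  train=None, seed: int = 0) -> SurveyForm:
    """Build the survey form for a fitted rule model.

    Either pass precomputed ``summaries`` (one per selected rule) or a
    training table to compute them from.  Item order is shuffled under
    ``seed`` and recorded on the form.
    """
    rules = model.rules if hasattr(model, "rules") else list(model)
    if summaries is None:
        if train is None:
            raise ValueError("need summaries or a training table")
        summaries = [summarize_subgroup(r, train) for r in rules]
    by_id = {s.rule_id: s for s in summaries}
    missing = [r.rule_id for r in rules if r.rule_id not in by_id]
    if missing:
        raise ValueError(f"missing summaries for rules: {missing}")
    if not rules:
        import warnings
        warnings.warn("no selected rules; survey form is empty")
    items = [by_id[r.rule_id] for r in rules]
    order = np.random.default_rng(seed).permutation(len(items))
    return SurveyForm([items[i] for i in order], seed=seed)


def ingest_responses(source, form: SurveyForm) -> pd.DataFrame:
    """Read and validate a long-format response table.

    ``source`` is a CSV path or DataFrame with columns expert_id, role,
    experience_band, rule_id, response.  Responses must be integers 1-5
    over the form's rule ids; exact duplicate rows collapse, conflicting
    duplicates (same expert & rule, different value) are an error.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table lacks columns: {missing}")
    df = df[RESPONSE_COLUMNS].drop_duplicates().reset_index(drop=True)

    errors = []
    resp = pd.to_numeric(df["response"], errors="coerce")
    bad = df.index[resp.isna() | (resp % 1 != 0) | (resp < 1) | (resp > 5)]
    for i in bad:
        errors.append(f"row {i}: response {df.loc[i, 'response']!r} "
                      "not an integer in 1..5")
    known = set(form.rule_ids)
    for i in df.index[~df["rule_id"].isin(known)]:
        errors.append(f"row {i}: unknown rule_id {df.loc[i, 'rule_id']!r}")
    dup = df.duplicated(subset=["expert_id", "rule_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["expert_id", "rule_id"]].drop_duplicates()
        for _, row in pairs.iterrows():
            errors.append(f"conflicting duplicate responses for expert "
                          f"{row['expert_id']!r}, rule {row['rule_id']!r}")
    if errors:
        raise ValueError("invalid responses:\n" + "\n".join(errors))
    df["response"] = resp.astype(int)
    return df


def aggregate_responses(responses: pd.DataFrame,
                        filter: Callable[[pd.Series], bool] | None = None,
                        ddof: int = 1) -> pd.DataFrame:
    """Per-rule mean and sample SD (n-1 denominator by default) of numeric
    Likert responses, over the full panel or a filtered subset.

    ``filter`` receives each response row (with role and experience_band)
    and keeps those returning True.  Every rule must retain at least one
    response after filtering.
    Returns a DataFrame indexed by rule_id with columns mean, sd, n.
    """
    df = responses
    if filter is not None:
        keep = df.apply(filter, axis=1)
        df = df[keep]
    all_rules = responses["rule_id"].unique()
    counts = df.groupby("rule_id")["response"].size()
    empty = [r for r in all_rules if counts.get(r, 0) == 0]
    if empty:
        raise ValueError(f"rules with zero responses after filtering: {empty}")
    g = df.groupby("rule_id")["response"]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=ddof).fillna(0.0),
                        "n": g.size()})
    return out.loc[list(dict.fromkeys(responses["rule_id"]))]
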