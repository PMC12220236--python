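"""Synthetic ICU-cohort and simulated-expert generator.

Emulates the data structure of a ventilated-patient cohort: one record per
4-hour window (windows start 12 h after intubation), numeric and
categorical features with baseline and two lagged copies, a per-window
binary outcome (successful extubation) drawn from a logistic model over
planted subgroup rules, a temporal 80/20 train/test split of the internal
cohort by intubation order, and an external cohort whose conditional
outcome distribution differs on designated "spurious" rules (rules whose
train-set effect vanishes or flips externally).

Expert panels are simulated from the *external-valid* risk of each rule's
subgroup: each expert's latent score per rule is the log relative risk of
the subgroup in the external cohort plus a shared bias and personal noise,
mapped through fixed cut-points onto the 1-5 Likert scale (1 = much higher
chance of success).  This makes the simulated experts a noisy oracle for
generalizable signal, which is the premise the method relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .rules import Rule, RuleCondition, build_rule_matrix

__all__ = [
    "PlantedRule",
    "CohortConfig",
    "ExpertPanelConfig",
    "CohortTable",
    "generate_cohort",
    "simulate_expert_panel",
    "calibrate_base_logit",
    "study_emulation_config",
    "default_panel_config",
]

RESERVED_COLUMNS = ("intubation_id", "window_index", "window_end_time",
                    "split", "outcome")
WINDOW_HOURS = 4
FIRST_WINDOW_END_HOURS = 12  # windows begin 12 h post-intubation

# Likert anchors: 1 = much higher, ..., 5 = much lower chance of success
LIKERT_LABELS = {1: "much higher", 2: "somewhat higher", 3: "no difference",
                 4: "somewhat lower", 5: "much lower"}


@dataclass(frozen=True)
class PlantedRule:
    """A subgroup rule with a log-odds outcome contribution that may differ
    between the internal and external cohorts.

    A rule is *spurious* when its training-cohort effect does not carry to
    the external cohort (zero or opposite sign there) — the synthetic
    analogue of an artifactual, non-generalizing association.
    """

    conditions: tuple[RuleCondition, ...]
    effect_train: float
    effect_external: float

    @property
    def spurious(self) -> bool:
        if self.effect_train == 0:
            return False
        return (self.effect_external == 0
                or np.sign(self.effect_external) != np.sign(self.effect_train))

    def as_rule(self, rule_id: str) -> Rule:
        return Rule(rule_id=rule_id, conditions=self.conditions)


@dataclass
class CohortConfig:
    n_intubations: int = 1173          # internal cohort (train + test)
    n_external_intubations: int = 263
    windows_min: int = 6
    windows_max: int = 72
    n_numeric_features: int = 8
    n_categorical_features: int = 2
    categorical_n_levels: int = 3
    n_lags: int = 2                    # lagged copies of each feature
    baseline_copy: bool = True
    feature_rho: float = 0.5           # within-intubation AR(1) of numerics
    planted_rules: tuple[PlantedRule, ...] = ()
    base_logit: float = 0.0
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_lags < 0:
            raise ValueError("n_lags must be >= 0")
        if self.windows_min < 1 or self.windows_max < self.windows_min:
            raise ValueError("invalid windows_min/windows_max")

    @property
    def numeric_names(self) -> list[str]:
        return [f"num{i}" for i in range(self.n_numeric_features)]

    @property
    def categorical_names(self) -> list[str]:
        return [f"cat{i}" for i in range(self.n_categorical_features)]

    @property
    def categorical_levels(self) -> dict[str, list[str]]:
        lv = [f"L{j}" for j in range(self.categorical_n_levels)]
        return {name: list(lv) for name in self.categorical_names}

    def validate_rules(self) -> None:
        base = set(self.numeric_names) | set(self.categorical_names)
        derived = set()
        for name in base:
            for lag in range(1, self.n_lags + 1):
                derived.add(f"{name}__lag{lag}")
            if self.baseline_copy:
                derived.add(f"{name}__baseline")
        known = base | derived
        for pr in self.planted_rules:
            for cond in pr.conditions:
                if cond.feature not in known:
                    raise ValueError(
                        f"planted rule references undefined feature "
                        f"{cond.feature!r}")


@dataclass
class ExpertPanelConfig:
    # role mix of the emulated panel: attending physicians, fellows,
    # registered nurses, respiratory therapists
    roles: tuple[tuple[str, str, int], ...] = (
        ("attending", ">10", 12), ("fellow", "3-5", 7),
        ("nurse", "6-10", 4), ("respiratory_therapist", "<3", 2))
    perception_noise_sd: float = 0.25
    shared_bias: float = 0.0
    likert_cutpoints: tuple[float, ...] = (-0.4, -0.1, 0.1, 0.4)
    seed: int = 0

    def __post_init__(self):
        if self.perception_noise_sd < 0:
            raise ValueError("perception_noise_sd must be >= 0")
        c = self.likert_cutpoints
        if len(c) != 4 or any(c[i] >= c[i + 1] for i in range(3)):
            raise ValueError("likert_cutpoints must be 4 strictly "
                             "increasing values")

    @property
    def n_experts(self) -> int:
        return sum(n for _, _, n in self.roles)


@dataclass
class CohortTable:
    """Windowed cohort records: one row per 4-hour window with cluster id,
    window index/time, features (incl. lag and baseline copies), binary
    outcome, and a split label in {train, test, external}."""

    df: pd.DataFrame
    feature_names: list[str]
    categorical_levels: dict[str, list[str]] = field(default_factory=dict)

    def split(self, label: str) -> "CohortTable":
        sub = self.df[self.df["split"] == label]
        if label != "external" and sub.empty:
            raise ValueError(f"no records with split {label!r}")
        return CohortTable(sub.reset_index(drop=True), self.feature_names,
                           self.categorical_levels)

    @property
    def train(self):
        return self.split("train")

    @property
    def test(self):
        return self.split("test")

    @property
    def external(self):
        return self.split("external")

    def outcome_rate(self, label: str | None = None) -> float:
        df = self.df if label is None else self.df[self.df["split"] == label]
        return float(df["outcome"].mean())

    def to_csv(self, path) -> None:
        cols = list(RESERVED_COLUMNS) + self.feature_names
        # shortest round-trip float rendering: reloading the CSV must
        # reproduce bit-identical features (rule thresholds compare exactly)
        self.df[cols].to_csv(path, index=False,
                             float_format=lambda x: repr(float(x)))

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, float_precision="round_trip")
        feats = [c for c in df.columns if c not in RESERVED_COLUMNS]
        cat = {c: sorted(df[c].dropna().unique())
               for c in feats if df[c].dtype == object}
        return cls(df, feats, cat)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _simulate_base_features(config: CohortConfig, n_intubations: int,
                            rng: np.random.Generator,
                            id_prefix: str) -> pd.DataFrame:
    """Per-window base features for one cohort; numerics follow a
    within-intubation AR(1), categoricals are iid across windows."""
    n_windows = rng.integers(config.windows_min, config.windows_max + 1,
                             size=n_intubations)
    total = int(n_windows.sum())
    iid = np.repeat([f"{id_prefix}{i:05d}" for i in range(n_intubations)],
                    n_windows)
    widx = np.concatenate([np.arange(k) for k in n_windows])

    rho = config.feature_rho
    num = np.empty((total, config.n_numeric_features))
    eps = rng.standard_normal((total, config.n_numeric_features))
    starts = np.concatenate([[0], np.cumsum(n_windows)[:-1]])
    for s, k in zip(starts, n_windows):
        x = eps[s]
        num[s] = x
        for t in range(1, k):
            x = rho * x + np.sqrt(1 - rho ** 2) * eps[s + t]
            num[s + t] = x

    data = {"intubation_id": iid, "window_index": widx,
            "window_end_time": FIRST_WINDOW_END_HOURS + WINDOW_HOURS * widx}
    for j, name in enumerate(config.numeric_names):
        data[name] = num[:, j]
    levels = [f"L{j}" for j in range(config.categorical_n_levels)]
    for name in config.categorical_names:
        data[name] = np.asarray(levels)[rng.integers(0, len(levels),
                                                     size=total)]
    return pd.DataFrame(data)


def _add_lags(df: pd.DataFrame, config: CohortConfig) -> list[str]:
    """Append lag-k and baseline copies per base feature; the first windows
    of an intubation backfill missing lags with the earliest value."""
    base = config.numeric_names + config.categorical_names
    g = df.groupby("intubation_id", sort=False)
    added = []
    for name in base:
        for lag in range(1, config.n_lags + 1):
            col = f"{name}__lag{lag}"
            df[col] = g[name].shift(lag)
            df[col] = df[col].fillna(g[name].transform("first"))
            added.append(col)
        if config.baseline_copy:
            col = f"{name}__baseline"
            df[col] = g[name].transform("first")
            added.append(col)
    return added


def _planted_linear_predictor(df: pd.DataFrame, config: CohortConfig,
                              external: bool) -> np.ndarray:
    lp = np.full(len(df), config.base_logit, dtype=float)
    if not config.planted_rules:
        return lp
    rules = [pr.as_rule(f"planted{i}")
             for i, pr in enumerate(config.planted_rules)]
    M = build_rule_matrix(rules, df).to_numpy(dtype=float)
    eff = np.array([pr.effect_external if external else pr.effect_train
                    for pr in config.planted_rules])
    return lp + M @ eff


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Generate internal (train/test by intubation order) and external
    cohorts with outcomes drawn from the planted-rule logistic model."""
    config.validate_rules()
    rng = np.random.default_rng(config.seed)
    frames = []
    for prefix, n, external in (("A", config.n_intubations, False),
                                ("B", config.n_external_intubations, True)):
        if n == 0:
            continue
        df = _simulate_base_features(config, n, rng, prefix)
        _add_lags(df, config)
        lp = _planted_linear_predictor(df, config, external)
        df["outcome"] = (rng.random(len(df)) < expit(lp)).astype(int)
        if external:
            df["split"] = "external"
        else:
            ids = df["intubation_id"].unique()  # generation (= temporal) order
            n_train = int(round(config.train_fraction * len(ids)))
            train_ids = set(ids[:n_train])
            df["split"] = np.where(df["intubation_id"].isin(train_ids),
                                   "train", "test")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    feats = [c for c in out.columns if c not in RESERVED_COLUMNS]
    levels = [f"L{j}" for j in range(config.categorical_n_levels)]
    cat_levels = {c: list(levels) for c in feats if out[c].dtype == object}
    return CohortTable(out, feats, cat_levels)


def calibrate_base_logit(config: CohortConfig, target_rate: float = 0.762,
                         n_probe_intubations: int = 400) -> float:
    """Base intercept such that the internal cohort's expected positive
    rate hits ``target_rate`` (solved on a probe sample of windows)."""
    probe = replace(config, n_intubations=n_probe_intubations,
                    n_external_intubations=0, base_logit=0.0)
    rng = np.random.default_rng(config.seed)
    df = _simulate_base_features(probe, n_probe_intubations, rng, "A")
    _add_lags(df, probe)
    lp = _planted_linear_predictor(df, probe, external=False)

    def gap(b):
        return float(expit(b + lp).mean()) - target_rate

    return float(brentq(gap, -20, 20, xtol=1e-8))


def study_emulation_config(seed: int = 0, calibrate: bool = True,
                           n_intubations: int = 1173,
                           n_external_intubations: int = 263,
                           n_spurious: int = 2, n_stable: int = 6,
                           spurious_effect: float = 2.0) -> CohortConfig:
    """Default study-scale configuration: 1173 internal intubations split
    80/20, 263 external, 8 planted rules of which 2 are spurious
    (train-only effects of ±``spurious_effect`` that vanish externally),
    intercept calibrated to a ~76.2% positive rate internally."""
    planted = []
    stable_effects = [1.2, -1.2, 0.9, -0.9, 0.7, -0.7, 0.5, -0.5]
    for i in range(n_stable):
        e = stable_effects[i % len(stable_effects)]
        cond = RuleCondition(f"num{i % 8}",
                             "numeric_gt" if e > 0 else "numeric_le",
                             threshold=0.6)
        planted.append(PlantedRule((cond,), e, e))
    for i in range(n_spurious):
        e = spurious_effect if i % 2 == 0 else -spurious_effect
        cond = RuleCondition(f"num{(n_stable + i) % 8}", "numeric_le",
                             threshold=-0.6)
        planted.append(PlantedRule((cond,), e, 0.0))
    cfg = CohortConfig(n_intubations=n_intubations,
                       n_external_intubations=n_external_intubations,
                       planted_rules=tuple(planted), seed=seed)
    if calibrate:
        cfg.base_logit = calibrate_base_logit(cfg)
    return cfg


def default_panel_config(seed: int = 0) -> ExpertPanelConfig:
    return ExpertPanelConfig(seed=seed)


# --------------------------------------------------------------------------
# expert-panel simulation
# --------------------------------------------------------------------------

def simulate_expert_panel(rules: Sequence[Rule], cohort: CohortTable,
                          config: ExpertPanelConfig) -> pd.DataFrame:
    """Simulate Likert responses (1-5) of an expert panel for each rule.

    Latent score per rule = log(subgroup risk / overall risk) in the
    *external* cohort, plus ``shared_bias`` and per-(expert, rule) Gaussian
    noise; cut-points map high latent relative risk to low Likert values
    (1 = much higher chance of success).  Rules with no firing external
    record fall back to the training-cohort risk with a warning.
    Returns the long-format response set: expert_id, role,
    experience_band, rule_id, response.
    """
    rng = np.random.default_rng(config.seed)
    train_df = cohort.train.df
    ext_df = cohort.df[cohort.df["split"] == "external"]
    if ext_df.empty:
        raise ValueError("cohort has no external split to anchor experts on")

    M_train = build_rule_matrix(rules, train_df)
    if (M_train.sum(axis=0) == 0).any():
        dead = [r.rule_id for r in rules if M_train[r.rule_id].sum() == 0]
        raise ValueError(f"rules with zero training support: {dead}")
    M_ext = build_rule_matrix(rules, ext_df)
    overall_ext = ext_df["outcome"].mean()
    overall_train = train_df["outcome"].mean()

    latent_base = np.empty(len(rules))
    for j, rule in enumerate(rules):
        fires = M_ext[rule.rule_id].to_numpy(dtype=bool)
        if fires.any():
            risk = ext_df.loc[fires, "outcome"].mean()
            latent_base[j] = _log_rr(risk, overall_ext)
        else:
            fires_tr = M_train[rule.rule_id].to_numpy(dtype=bool)
            risk = train_df.loc[fires_tr, "outcome"].mean()
            warnings.warn(f"rule {rule.rule_id} has no external support; "
                          "expert latent anchored on training risk")
            latent_base[j] = _log_rr(risk, overall_train)

    experts = []
    i = 0
    for role, band, count in config.roles:
        for _ in range(count):
            experts.append((f"E{i:03d}", role, band))
            i += 1

    cut = np.asarray(config.likert_cutpoints)
    rows = []
    for expert_id, role, band in experts:
        noise = (rng.standard_normal(len(rules)) * config.perception_noise_sd
                 if config.perception_noise_sd > 0 else np.zeros(len(rules)))
        latent = latent_base + config.shared_bias + noise
        # number of cutpoints strictly below the latent score; latent > c4
        # maps to 1 ("much higher"), latent <= c1 maps to 5 ("much lower")
        resp = 5 - np.searchsorted(cut, latent, side="left")
        for rule, r in zip(rules, resp):
            rows.append((expert_id, role, band, rule.rule_id, int(r)))
    return pd.DataFrame(rows, columns=["expert_id", "role",
                                       "experience_band", "rule_id",
                                       "response"])


def _log_rr(risk: float, overall: float) -> float:
    if overall <= 0:
        raise ValueError("overall outcome rate is zero; latent scale undefined")
    if risk <= 0:
        return -np.inf  # zero subgroup risk: unboundedly lower chance
    return float(np.log(risk / overall))
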