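"""Internal/external evaluation: AUCs, paired bootstrap CIs, change scores
and difference-in-differences vs the RuleFit baseline.

AUC is the Mann-Whitney probability P(score+ > score-) + 0.5 P(=).  CIs
are percentile bootstrap over resampled units — intubations by default
(windows within an intubation are dependent), optionally windows.  The
change score of a model is auc_external - auc_test (negative = performance
drop out of distribution); its difference from the baseline's change score
is the difference-in-differences (positive = the model generalizes better
than the baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .rules import predict_scores

__all__ = [
    "BootstrapSpec",
    "roc_auc",
    "bootstrap_paired_diff",
    "change_score",
    "did_vs_baseline",
    "full_report",
    "EvalReport",
]


@dataclass
class BootstrapSpec:
    n_iterations: int = 2000
    resample_unit: str = "intubation"   # or "window"
    ci_method: str = "percentile"
    seed: int = 0
    max_redraws: int = 100              # single-class replicates redrawn

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.resample_unit not in ("intubation", "window"):
            raise ValueError("resample_unit must be 'intubation' or 'window'")
        if self.ci_method != "percentile":
            raise ValueError("only percentile CIs are implemented")


def roc_auc(scores, labels) -> float:
    """AUC with ties counted 1/2 (Mann-Whitney convention).

    Rank form of the statistic: (R1 - n1(n1+1)/2) / (n1 n0) with midranks,
    which equals P(score+ > score-) + 0.5 P(score+ = score-).
    """
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0 or n1 + n0 != len(labels):
        raise ValueError("labels must contain both classes (0 and 1)")
    r = rankdata(np.asarray(scores, dtype=float))
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _as_frame(table) -> pd.DataFrame:
    return table.df if hasattr(table, "df") else table


class _Resampler:
    """Unit resampler with the intubation-group index built once."""

    def __init__(self, df: pd.DataFrame, unit: str):
        self.unit = unit
        self.n = len(df)
        if unit == "intubation":
            inverse = pd.factorize(df["intubation_id"])[0]
            order = np.argsort(inverse, kind="stable")
            bounds = np.flatnonzero(np.diff(inverse[order])) + 1
            self.groups = np.split(order, bounds)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        if self.unit == "window":
            return rng.integers(0, self.n, size=self.n)
        take = rng.integers(0, len(self.groups), size=len(self.groups))
        return np.concatenate([self.groups[t] for t in take])


def _resample_indices(df: pd.DataFrame, unit: str,
                      rng: np.random.Generator) -> np.ndarray:
    return _Resampler(df, unit).draw(rng)


def _bootstrap_stats(stat_of_idx, df, spec: BootstrapSpec) -> np.ndarray:
    """Evaluate a per-replicate statistic over bootstrap resamples; a
    replicate where the statistic is undefined (single class) is redrawn
    up to ``max_redraws`` times."""
    rng = np.random.default_rng(spec.seed)
    sampler = _Resampler(df, spec.resample_unit)
    out = np.empty(spec.n_iterations)
    for b in range(spec.n_iterations):
        for attempt in range(spec.max_redraws + 1):
            idx = sampler.draw(rng)
            try:
                out[b] = stat_of_idx(idx)
                break
            except ValueError:
                if attempt == spec.max_redraws:
                    raise ValueError(
                        "bootstrap replicate single-class after "
                        f"{spec.max_redraws} redraws")
                warnings.warn("single-class bootstrap replicate redrawn")
    return out


def _percentile_ci(samples: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(samples, 2.5)),
            float(np.percentile(samples, 97.5)))


def bootstrap_paired_diff(statistic_fn, model_a, model_b, table,
                          spec: BootstrapSpec) -> tuple[float, tuple]:
    """Point estimate and percentile CI of statistic(model_a) -
    statistic(model_b) under paired resampling of ``table``.

    ``statistic_fn(scores, labels)`` is evaluated for both models on each
    replicate (same resample — paired).
    """
    df = _as_frame(table)
    y = df["outcome"].to_numpy(dtype=int)
    sa = predict_scores(model_a, df)
    sb = predict_scores(model_b, df)
    point = statistic_fn(sa, y) - statistic_fn(sb, y)

    def stat(idx):
        return statistic_fn(sa[idx], y[idx]) - statistic_fn(sb[idx], y[idx])

    samples = _bootstrap_stats(stat, df, spec)
    return float(point), _percentile_ci(samples)


def change_score(model, test_table, external_table) -> float:
    """auc_external - auc_test for one model (negative = drop under the
    external distribution)."""
    t, e = _as_frame(test_table), _as_frame(external_table)
    auc_t = roc_auc(predict_scores(model, t), t["outcome"])
    auc_e = roc_auc(predict_scores(model, e), e["outcome"])
    return float(auc_e - auc_t)


def did_vs_baseline(model, baseline, test_table, external_table,
                    spec: BootstrapSpec) -> tuple[float, tuple]:
    """Difference-in-differences: change_score(model) -
    change_score(baseline), with a percentile CI from joint paired
    resampling of the test and external tables."""
    t, e = _as_frame(test_table), _as_frame(external_table)
    yt, ye = t["outcome"].to_numpy(int), e["outcome"].to_numpy(int)
    smt, sme = predict_scores(model, t), predict_scores(model, e)
    sbt, sbe = predict_scores(baseline, t), predict_scores(baseline, e)
    point = ((roc_auc(sme, ye) - roc_auc(smt, yt))
             - (roc_auc(sbe, ye) - roc_auc(sbt, yt)))

    rng = np.random.default_rng(spec.seed)
    spec_t = BootstrapSpec(spec.n_iterations, spec.resample_unit,
                           spec.ci_method, int(rng.integers(2 ** 31)),
                           spec.max_redraws)
    spec_e = BootstrapSpec(spec.n_iterations, spec.resample_unit,
                           spec.ci_method, int(rng.integers(2 ** 31)),
                           spec.max_redraws)
    rng_t = np.random.default_rng(spec_t.seed)
    rng_e = np.random.default_rng(spec_e.seed)
    sampler_t = _Resampler(t, spec.resample_unit)
    sampler_e = _Resampler(e, spec.resample_unit)
    samples = np.empty(spec.n_iterations)
    for b in range(spec.n_iterations):
        for attempt in range(spec.max_redraws + 1):
            it = sampler_t.draw(rng_t)
            ie = sampler_e.draw(rng_e)
            try:
                samples[b] = ((roc_auc(sme[ie], ye[ie])
                               - roc_auc(smt[it], yt[it]))
                              - (roc_auc(sbe[ie], ye[ie])
                                 - roc_auc(sbt[it], yt[it])))
                break
            except ValueError:
                if attempt == spec.max_redraws:
                    raise
                warnings.warn("single-class bootstrap replicate redrawn")
    return float(point), _percentile_ci(samples)


def _youden_threshold(scores, labels) -> float:
    fpr, tpr, thr = roc_curve(labels, scores)
    return float(thr[np.argmax(tpr - fpr)])


def _secondary_metrics(scores, labels, threshold: float) -> dict:
    labels = np.asarray(labels)
    pred = np.asarray(scores) >= threshold
    pos, neg = labels == 1, labels == 0
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec_ = float((~pred[neg]).mean()) if neg.any() else np.nan
    return {"sensitivity": sens, "specificity": spec_,
            "balanced_accuracy": (sens + spec_) / 2}


@dataclass
class EvalReport:
    table: pd.DataFrame                     # one row per model
    roc_coordinates: pd.DataFrame           # model, split, fpr, tpr, threshold
    threshold: float
    baseline: str = "RuleFit"

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_json(self) -> str:
        return self.table.reset_index().to_json(orient="records", indent=1)


def full_report(models: dict, tables, spec: BootstrapSpec,
                baseline: str = "RuleFit") -> EvalReport:
    """Table-3-style report for a model set vs a baseline.

    ``models`` maps name -> fitted model (must contain ``baseline``);
    ``tables`` provides train/test/external splits (a CohortTable or a
    dict of DataFrames).  Per model: test and external AUC, AUC
    differences from the baseline with bootstrap CIs, change score, and
    difference-in-differences with CI; secondary metrics at the threshold
    maximizing training Youden's J for that model.
    """
    if baseline not in models:
        raise ValueError(f"baseline {baseline!r} not among models")
    if hasattr(tables, "split"):
        train, test, ext = tables.train.df, tables.test.df, tables.external.df
    else:
        train, test, ext = (_as_frame(tables["train"]),
                            _as_frame(tables["test"]),
                            _as_frame(tables["external"]))
    base = models[baseline]
    rng = np.random.default_rng(spec.seed)
    rows, roc_rows = [], []
    thr_base = _youden_threshold(predict_scores(base, train),
                                 train["outcome"])
    for name, model in models.items():
        auc_t = roc_auc(predict_scores(model, test), test["outcome"])
        auc_e = roc_auc(predict_scores(model, ext), ext["outcome"])
        cs = change_score(model, test, ext)
        row = {"model": name, "auc_test": auc_t, "auc_external": auc_e,
               "change_score": cs}
        if name == baseline:
            row.update(diff_test=0.0, diff_test_lo=np.nan,
                       diff_test_hi=np.nan, diff_external=0.0,
                       diff_external_lo=np.nan, diff_external_hi=np.nan,
                       did=0.0, did_lo=np.nan, did_hi=np.nan)
        else:
            sub = lambda: BootstrapSpec(spec.n_iterations,
                                        spec.resample_unit, spec.ci_method,
                                        int(rng.integers(2 ** 31)),
                                        spec.max_redraws)
            dt, ci_t = bootstrap_paired_diff(roc_auc, model, base, test,
                                             sub())
            de, ci_e = bootstrap_paired_diff(roc_auc, model, base, ext,
                                             sub())
            did, ci_d = did_vs_baseline(model, base, test, ext, sub())
            row.update(diff_test=dt, diff_test_lo=ci_t[0],
                       diff_test_hi=ci_t[1], diff_external=de,
                       diff_external_lo=ci_e[0], diff_external_hi=ci_e[1],
                       did=did, did_lo=ci_d[0], did_hi=ci_d[1])
        thr = _youden_threshold(predict_scores(model, train),
                                train["outcome"])
        for split_name, df in (("test", test), ("external", ext)):
            scores = predict_scores(model, df)
            row.update({f"{k}_{split_name}": v for k, v in
                        _secondary_metrics(scores, df["outcome"], thr)
                        .items()})
            fpr, tpr, t = roc_curve(df["outcome"], scores)
            roc_rows.append(pd.DataFrame(
                {"model": name, "split": split_name, "fpr": fpr, "tpr": tpr,
                 "threshold": t}))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")
    return EvalReport(table, pd.concat(roc_rows, ignore_index=True),
                      thr_base, baseline)
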