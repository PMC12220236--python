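"""End-to-end orchestration with deterministic seeding and artifact
provenance.

Stages: simulate -> fit -> survey -> (panel simulation or external
responses) -> ingest -> discord -> refit -> evaluate.  Each stage reads
and writes documented CSV/JSON artifacts, so a human expert panel can
replace the simulator mid-pipeline by supplying a responses CSV.  Stage
seeds derive purely from (global_seed, stage name); the manifest records a
hash of every artifact, making identical-config reruns byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import discordance, elicitation, evaluation, refit, synthetic
from .rules import HyperparamGrid, RuleFitHyperparams, build_rule_matrix, \
    fit_rulefit, tune_hyperparameters
from .synthetic import CohortConfig, CohortTable, ExpertPanelConfig

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_config",
           "derive_seed"]

logger = logging.getLogger("eaml")

STAGES = ("simulate", "fit", "survey", "panel", "ingest", "discord",
          "refit", "evaluate")


def derive_seed(global_seed: int, stage: str) -> int:
    """Pure (global_seed, stage) -> stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    panel: ExpertPanelConfig = field(default_factory=ExpertPanelConfig)
    hyperparams: RuleFitHyperparams = field(
        default_factory=RuleFitHyperparams)
    grid: HyperparamGrid | None = None     # when set, tune before fitting
    hard_ks: tuple[int, ...] = refit.DEFAULT_K_GRID
    include_soft: bool = True
    bootstrap: evaluation.BootstrapSpec = field(
        default_factory=evaluation.BootstrapSpec)
    responses_file: str | None = None      # real expert responses (CSV)
    calibrate_rate: float | None = 0.762   # target positive rate; None = off
    output_dir: str = "eaml_run"
    global_seed: int = 0


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "panel": ExpertPanelConfig,
    "hyperparams": RuleFitHyperparams,
    "grid": HyperparamGrid,
    "bootstrap": evaluation.BootstrapSpec,
}
_SCALAR_KEYS = {"hard_ks", "include_soft", "responses_file",
                "calibrate_rate", "output_dir", "global_seed"}


def validate_config(source) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file, mapping, or empty input.

    Unknown keys and invalid ranges are collected and reported together.
    """
    if source is None:
        raw = {}
    elif isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
    errors: list[str] = []
    kwargs: dict = {}
    for key, val in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(val) - names
            if unknown:
                errors.append(f"{key}: unknown keys {sorted(unknown)}")
                continue
            try:
                coerced = {
                    k: tuple(tuple(x) if isinstance(x, list) else x
                             for x in v) if isinstance(v, list) else v
                    for k, v in val.items()}
                kwargs[key] = cls(**coerced)
            except (TypeError, ValueError) as e:
                errors.append(f"{key}: {e}")
        elif key in _SCALAR_KEYS:
            kwargs[key] = tuple(val) if isinstance(val, list) else val
        else:
            errors.append(f"unknown top-level key {key!r}")
    cfg = None
    if not errors:
        try:
            cfg = RunConfig(**kwargs)
        except (TypeError, ValueError) as e:
            errors.append(str(e))
    if cfg is not None:
        # k feasibility vs the selected-rule count is checked at refit time
        for k in cfg.hard_ks:
            if k < 0:
                errors.append(f"hard k must be >= 0, got {k}")
    if errors:
        raise ValueError("invalid configuration:\n" +
                         "\n".join(f"  - {e}" for e in errors))
    logger.info("resolved config: %s", cfg)
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)
    package_version: str = "0.1.0"

    def record(self, stage: str, seed: int | None, outputs: dict):
        self.stages[stage] = {
            "seed": seed,
            "outputs": {name: _hash_file(path) for name, path in
                        outputs.items()},
            "files": {name: str(path) for name, path in outputs.items()},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def to_json(self) -> str:
        d = {"config_hash": self.config_hash,
             "package_version": self.package_version,
             "stages": self.stages}
        return json.dumps(d, indent=1)

    def comparable(self) -> dict:
        """Manifest content without timestamps or absolute paths, for
        reproducibility checks."""
        return {"config_hash": self.config_hash,
                "stages": {s: {k: v for k, v in d.items()
                               if k not in ("timestamp", "files")}
                           for s, d in self.stages.items()}}


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    # output_dir is a run location, not part of the scientific configuration
    blob = repr(dataclasses.replace(config, output_dir="")).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig, output_dir=None) -> RunManifest:
    """Execute every stage in order, writing artifacts and a manifest.

    When ``config.responses_file`` is given the simulated-panel stage is
    skipped and the external responses are ingested instead.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(config))
    gs = config.global_seed

    # -- simulate ----------------------------------------------------------
    seed = derive_seed(gs, "simulate")
    cohort_cfg = dataclasses.replace(config.cohort, seed=seed)
    if config.calibrate_rate is not None:
        cohort_cfg.base_logit = synthetic.calibrate_base_logit(
            cohort_cfg, config.calibrate_rate)
    cohort = synthetic.generate_cohort(cohort_cfg)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path)
    manifest.record("simulate", seed, {"cohort": cohort_path})
    logger.info("simulated %d windows (%d train / %d test / %d external)",
                len(cohort.df), len(cohort.train.df), len(cohort.test.df),
                len(cohort.external.df))

    # -- fit ---------------------------------------------------------------
    seed = derive_seed(gs, "fit")
    hp = config.hyperparams
    if config.grid is not None:
        hp = tune_hyperparameters(cohort.train, config.grid)
        logger.info("tuned hyperparameters: %s", hp)
    model = fit_rulefit(cohort.train, hp, seed=seed)
    model_path = out / "rulefit_model.json"
    model_path.write_text(model.to_json())
    manifest.record("fit", seed, {"rulefit_model": model_path})
    logger.info("rulefit selected %d of %d candidate rules",
                len(model.selected_rules), len(model.all_rules))

    # -- survey ------------------------------------------------------------
    seed = derive_seed(gs, "survey")
    form = elicitation.render_survey(model, train=cohort.train, seed=seed)
    survey_json = out / "survey.json"
    survey_json.write_text(form.to_json())
    survey_md = out / "survey.md"
    survey_md.write_text(form.to_markdown())
    manifest.record("survey", seed, {"survey_json": survey_json,
                                     "survey_md": survey_md})

    # -- panel / ingest ----------------------------------------------------
    responses_path = out / "responses.csv"
    if config.responses_file:
        raw = pd.read_csv(config.responses_file)
        responses = elicitation.ingest_responses(raw, form)
        responses.to_csv(responses_path, index=False)
        manifest.record("ingest", None, {"responses": responses_path})
        manifest.stages["ingest"]["source"] = "external responses"
        logger.info("ingested %d external responses", len(responses))
    else:
        seed = derive_seed(gs, "panel")
        panel_cfg = dataclasses.replace(config.panel, seed=seed)
        simulated = synthetic.simulate_expert_panel(model.selected_rules,
                                                    cohort, panel_cfg)
        simulated.to_csv(responses_path, index=False)
        responses = elicitation.ingest_responses(simulated, form)
        manifest.record("panel", seed, {"responses": responses_path})
        manifest.stages["panel"]["source"] = "simulated panel"
        logger.info("simulated %d responses from %d experts",
                    len(responses), panel_cfg.n_experts)

    # -- discord -----------------------------------------------------------
    agg = elicitation.aggregate_responses(responses)
    assessments = discordance.assessment_table(model.selected_rules,
                                               cohort.train, agg)
    assess_path = out / "assessments.csv"
    assessments.to_csv(assess_path,
                       float_format=lambda x: repr(float(x)))
    manifest.record("discord", None, {"assessments": assess_path})
    conc = discordance.concordance_summary(assessments)
    logger.info("model-expert concordance R^2 = %s", conc.r_squared)

    # -- refit -------------------------------------------------------------
    seed = derive_seed(gs, "refit")
    matrix = build_rule_matrix(model.selected_rules, cohort.train)
    y = cohort.train.df["outcome"]
    models: dict[str, object] = {"RuleFit": model}
    eaml_models: dict[str, refit.EAMLModel] = {}
    if config.include_soft:
        eaml_models["soft"] = refit.soft_eaml(matrix, y, assessments, model,
                                              seed=seed)
    for k in config.hard_ks:
        if k >= len(model.selected_rules):
            logger.warning("skipping hard-%d: only %d selected rules", k,
                           len(model.selected_rules))
            continue
        eaml_models[f"hard-{k}"] = refit.hard_eaml(matrix, y, assessments,
                                                   model, k, seed=seed)
    models.update(eaml_models)
    for name, m in eaml_models.items():
        if m.provenance.get("excluded_rule_ids"):
            logger.info("%s excluded rules: %s", name,
                        m.provenance["excluded_rule_ids"])
    eaml_path = out / "eaml_models.json"
    eaml_path.write_text(refit.models_to_json(eaml_models))
    manifest.record("refit", seed, {"eaml_models": eaml_path})

    # -- evaluate ----------------------------------------------------------
    seed = derive_seed(gs, "evaluate")
    spec = dataclasses.replace(config.bootstrap, seed=seed)
    report = evaluation.full_report(models, cohort, spec)
    report_csv = out / "report.csv"
    report.to_csv(report_csv)
    report_json = out / "report.json"
    report_json.write_text(report.to_json())
    roc_csv = out / "roc_coordinates.csv"
    report.roc_coordinates.to_csv(roc_csv, index=False)
    manifest.record("evaluate", seed, {"report_csv": report_csv,
                                       "report_json": report_json,
                                       "roc_coordinates": roc_csv})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest
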