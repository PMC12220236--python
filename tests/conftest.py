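import pytest

from eaml.discordance import assessment_table
from eaml.elicitation import aggregate_responses
from eaml.rules import RuleFitHyperparams, fit_rulefit
from eaml.synthetic import (ExpertPanelConfig, generate_cohort,
                            simulate_expert_panel, study_emulation_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down study-emulation cohort (150 internal / 60 external
    intubations, short stays) shared by the downstream-stage tests."""
    cfg = study_emulation_config(seed=7, n_intubations=150,
                                 n_external_intubations=60)
    cfg.windows_min, cfg.windows_max = 3, 8
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    hp = RuleFitHyperparams(learning_rate=0.1, num_leaves=4, n_trees=24,
                            lasso_lambda=3e-3)
    return fit_rulefit(small_cohort.train, hp, seed=7)


@pytest.fixture(scope="session")
def small_responses(small_cohort, small_model):
    panel = ExpertPanelConfig(perception_noise_sd=0.25, seed=11)
    return simulate_expert_panel(small_model.selected_rules, small_cohort,
                                 panel)


@pytest.fixture(scope="session")
def small_assessments(small_cohort, small_model, small_responses):
    agg = aggregate_responses(small_responses)
    return assessment_table(small_model.selected_rules, small_cohort.train,
                            agg)
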