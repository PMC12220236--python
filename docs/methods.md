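# Methods

## The problem

Deciding when a mechanically ventilated child is ready for extubation is
largely a matter of individual clinician judgment. A prediction model
trained on electronic-health-record data can integrate far more inputs
than a single bedside test, but it can also learn artifacts of its
training site — associations that do not generalize to another unit.
Expert-augmented machine learning (EAML) addresses this by putting
clinicians in the loop between model fitting and deployment: an
interpretable rule-ensemble model is fit first, clinicians rate each
selected rule's subgroup, and the model is re-regularized wherever its
ranking of subgroups disagrees with the expert consensus.

This package implements the full procedure — rule-ensemble baseline,
survey construction and ingestion, rank discordance, soft/hard
re-regularization, and internal/external evaluation — together with a
synthetic cohort and simulated-expert generator, because the motivating
EHR data cannot be shared. Every stage reads and writes plain CSV/JSON
artifacts, so a real expert panel can replace the simulator by supplying
a responses file.

## Synthetic cohort generator

`eaml.synthetic` emulates the structure of a two-site paediatric ICU
cohort:

* One record per 4-hour time window, windows beginning 12 h after
  intubation; the intubation is the cluster unit.
* Numeric features follow a within-intubation AR(1) (default
  `feature_rho = 0.5`, a realistic persistence for vital-sign-like
  quantities); categorical features are drawn uniformly per window.
* Each feature also carries two lagged copies (`__lag1`, `__lag2`) and a
  baseline copy (`__baseline`). Missing lags at the first windows are
  backfilled with the earliest observed value rather than marked missing.
* The binary outcome (successful extubation) is drawn per window from
  `Bernoulli(logistic(base_logit + Σ effect_c · 1[rule_c fires]))`, where
  the planted rules' effects may differ between the internal and
  external cohorts. A rule whose training effect vanishes or flips
  externally is *spurious* — the synthetic analogue of a site artifact.
* The internal cohort is split 80/20 into train/test by intubation
  *order*, standing in for the calendar-date split of a real study; the
  external cohort is a separate site.
* `study_emulation_config()` reproduces the emulated study scale: 1173
  internal intubations, 263 external, 8 planted rules (6 stable, 2
  spurious with train-only log-odds ±2), and an intercept calibrated by
  root-finding so the internal positive rate is ≈ 76.2% — the outcome
  prevalence the method is meant to operate at.

Outcomes are drawn independently across windows given the features; the
real 12-hour outcome time-shift is a labelling convention the refit
mathematics never sees (it consumes only features, outcome and cluster
id). Consequently within-intubation outcome autocorrelation beyond what
the AR(1) features induce is not modelled, and the generator makes no
attempt at physiologic realism: passing tests demonstrate the method's
statistical behaviour under its stated assumptions, not clinical
performance on real patients.

### Simulated experts

Experts are modelled as noisy oracles for *generalizable* risk. Each
expert's latent score for a rule is the log relative risk of the rule's
subgroup in the external cohort, plus a panel-wide `shared_bias` and a
per-(expert, rule) Gaussian perception noise (default SD 0.25). The
latent score is mapped to the 1–5 Likert scale (1 = much higher chance of
success) through symmetric cut-points (−0.4, −0.1, 0.1, 0.4) on the
log-relative-risk scale, keeping "no difference" centred. The default
panel mirrors a realistic multidisciplinary mix: 12 attending physicians,
7 fellows, 4 nurses, 2 respiratory therapists (25 experts).

This design encodes the method's central premise — that expert consensus
carries information about out-of-sample validity that the training data
cannot. When that premise fails (experts sharing the training set's bias,
modelled via `shared_bias`), EAML cannot help; the generator makes that
failure mode expressible but it is not the default condition.

## Rule-ensemble baseline

`eaml.rules` fits gradient-boosted shallow trees (LightGBM), converts
them to conjunctive rules, and selects a sparse subset by L1-penalized
logistic regression on the Boolean rule-activation matrix.

* Rules are taken from **all** nodes below each root (internal and leaf),
  following the original rule-ensemble formulation; `leaves_only=True` is
  available. Conditions on the same feature along a path merge to the
  tightest interval, and exact duplicates are removed with a
  deterministic (tree index, emission order) ordering.
* Categorical features are one-hot encoded for the boosting stage and
  splits on dummy columns are translated back into `categorical_in`
  conditions on the original feature, so rules read as level-set
  membership.
* The design matrix contains rules only (no linear terms), and the
  Boolean columns are **not** standardized: rules share the {0,1} scale,
  and standardizing would silently reweight the penalty by support.
* The L1 fit minimizes `(1/n) Σ logloss + λ‖β‖₁` with an unpenalized
  intercept, solved by FISTA (accelerated proximal gradient with
  function-value restart). Soft-thresholding gives exact zeros and the
  solver is well behaved across the whole λ range, including the
  full-shrinkage regime where the model must fall back to the base rate.
  λ is chosen by k-fold cross-validation maximizing AUC when not fixed,
  with ties broken toward the sparser model.
* Boosting defaults (32 trees, ≤4 leaves, learning rate 0.1) put the
  candidate-rule count near one hundred at the emulated study scale —
  a survey-sized rule set; all are configurable, and
  `tune_hyperparameters` grid-searches learning rate, leaf count and λ
  by intubation-level cross-validation (ties toward fewer leaves, then
  smaller learning rate).
* Class imbalance is left unweighted.

## Elicitation

`eaml.elicitation` renders one survey item per selected rule: for each
variable the rule references, the median (min, max) for numeric or the
mode and level set for categorical, side by side for the rule's subgroup
and the full training sample, with the fixed question stem and the five
Likert anchors. Item order is randomized once per form under a recorded
seed. Responses are validated (integers 1–5, known rule ids, no
conflicting duplicates) and aggregated per rule to the arithmetic mean
and sample SD (n−1 denominator; a population-SD flag exists). An optional
row predicate restricts aggregation to a subpanel, e.g. attending
physicians only.

## Discordance

Both parties rank the selected rules by increasing chance of success:
the model by training-set empirical risk (subgroup outcome rate), the
experts by decreasing mean Likert response. Ties receive average
(fractional) ranks, which preserves `Σ delta_rank = 0` exactly. Then

    delta_rank          = model_rank − expert_rank
    delta_rank_over_sd  = delta_rank / max(expert_sd, sd_floor)

Negative values mean the model rated the subgroup less likely to succeed
than the experts did, and a unanimous panel (small SD) amplifies a given
rank gap — penalization is strongest where experts agree most. A
unanimous panel has SD 0, which no published analysis encounters but a
simulation can; the SD floor is the smallest positive SD observed across
rules (fallback 0.1 if all are zero), with a warning. Concordance is
summarized by the OLS R² of mean expert response on empirical risk.

## Re-regularization (the EAML refit)

Rule definitions and activation matrices are frozen after selection; the
refit changes only coefficients and (for hard variants) inclusion. The
core fit minimizes

    (1/n) Σ logloss  +  λ Σ_j p_j β_j²

with an unpenalized intercept, by L-BFGS on the exact objective. Per-rule
penalty factors make this a glmnet-style `penalty.factor` ridge; scaling
column j by 1/√p_j and fitting a uniform ridge is algebraically
equivalent for p_j > 0, but the direct form also covers p_j = 0 (an
exactly unpenalized coefficient).

* **Soft EAML**: `p_j = |delta_rank_over_sd_j|`, normalized to mean 1
  over the selected rules so λ remains comparable across variants. Note
  a consequence of the normalization: as one rule's raw discordance grows
  without bound its normalized factor saturates at R (the rule count), so
  the exact "coefficient → 0" limit holds for the unnormalized core fit,
  while the normalized soft model approaches it only up to the factor
  R·λ.
* **Hard-k EAML**: drop the k rules with largest `|delta_rank_over_sd|`
  (ties: larger `|delta_rank|`, then rule id), then a uniform ridge
  refit. The default k grid {1, 3, 5, 7, 10, 11} mirrors a
  histogram-guided choice; any k below the rule count is accepted.
* The refit is logistic-linked (the outcome is binary and evaluated by
  AUC); λ is re-tuned by CV per variant by default and fixable.

## Evaluation

AUC is the Mann–Whitney statistic with ties counted ½, computed in rank
form. Confidence intervals are 95% percentile bootstrap with 2000
iterations per pairwise comparison; the resampling unit is the
intubation by default (windows within an intubation are dependent), with
window-level resampling available. Per model the report gives test and
external AUC, AUC differences from the baseline with CIs, the change
score `auc_external − auc_test`, and the difference-in-differences
(model change score minus baseline change score, positive = better
generalization), plus sensitivity/specificity/balanced accuracy at the
threshold maximizing training-set Youden's J, and ROC coordinates for
plotting. Bootstrap replicates that lose a class are redrawn with a
capped retry count.

## The generalization experiment

`eaml.experiments.generalization_experiment` repeats the whole method
across seeds at a reduced scale chosen to keep a 50-replicate run in the
low minutes on one CPU: 1000 internal intubations (→ 800 train / 200
test), 250 external, 4–12 windows per intubation, 2 spurious planted
rules (train-only log-odds ∓2) among 6 stable ones, and a 25-expert
panel with perception noise 0.25.

Two design choices matter here:

* **Stump trees.** The planted rules are single conditions, so depth-1
  trees express the generative truth exactly and keep spurious and
  stable features in separate selected rules. This is the regime the
  method describes — a few identifiable discrepant rules. With deeper
  trees almost every rule mixes spurious and stable conditions and no
  small exclusion set can remove the spurious reliance; that measures
  feature entanglement of the learner, not the value of expert feedback.
* **Covering k.** The hard exclusion count is the smallest element of
  the default grid whose most-discrepant-first exclusion set covers both
  spurious rules' best-matching selected proxies (Jaccard overlap of
  training firing sets), capped at the grid maximum. This mirrors
  choosing k from the discordance histogram rather than fixing it
  blindly.

Each replicate records test/external AUC for the baseline and the hard
and soft refits, change scores and difference-in-differences. The
summary quantities are the fraction of seeds where the hard refit's
external AUC is at least the baseline's, and the mean
difference-in-differences.

## Numerical conventions

* All randomness flows from explicit seeds; pipeline stage seeds derive
  purely from `(global_seed, stage name)` via SHA-256 and stay below
  2^31. Identical configurations reproduce identical artifacts.
* Numeric splits use closed-left `≤ / >` semantics matching the tree
  library; thresholds are kept at full precision and rendered at display
  precision only.
* Artifact CSVs are written with shortest-round-trip float rendering and
  read with round-trip parsing, so a stage re-run from files reproduces
  the in-memory results to the last bit (up to the one-ulp differences
  inherent in alternative summation orders).
* `delta_rank_over_sd` is rounded to one decimal in rendered tables and
  carried at full precision everywhere else.
* FISTA runs to a 1e-9 step/objective tolerance; the ridge refit L-BFGS
  to ftol 1e-12. These support the documented identity checks (equal
  penalty factors ≡ uniform ridge to 1e-6; λ = 0 ≡ the unpenalized MLE
  to 1e-4).

## Concordance under strong planted artifacts

The scatter of mean expert response against training empirical risk is
summarized by an overall OLS R². In the synthetic emulation this value
is *low* (≈ 0.05 with stump trees, near zero with multi-leaf trees at
the study scale), even though the non-spurious rules line up well
(R² ≈ 0.6 after dropping the most discrepant rules). The planted
spurious effects are deliberately strong (train-only log-odds of ±2, so
the generalization experiment has a measurable signal), which makes the
spurious subgroups severe outliers on the concordance scatter; deeper
trees additionally smear those features into most selected rules. A
cohort whose artifacts are weak would show high overall concordance with
a few outliers instead. The concordance statistic is reported as
computed; it should be read jointly with the discordance table, which is
what the refit actually consumes.

## Known limitations

* The generator's independence of outcomes across windows understates
  the clustering a real cohort would show; the cluster bootstrap is
  exercised by construction, not stressed.
* Simulated experts are anchored on the *empirical* external risk of the
  finite external cohort, so their information content carries that
  cohort's sampling noise.
* The soft variant's mean-1 normalization bounds how strongly a single
  rule can be suppressed (see above); with many strongly discrepant
  rules the hard variant is the sharper instrument.
* Whether to resample windows or intubations in the bootstrap, and
  whether the original ridge refit was logistic- or identity-linked, are
  not determinable from the motivating analysis; the defaults here are
  intubation-level resampling and a logistic link, both configurable
  (identity link excepted — only the logistic link is implemented).
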