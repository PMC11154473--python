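# Methods

## Problem and scope

`survbias` quantifies the stability of binary mental-health classifiers (MDD and
GAD outcomes) when self-reported survey answers are corrupted by subjective
response errors. The package covers the full protocol — cohort synthesis, error
injection, model fitting, paired cross-validated evaluation, and per-feature
sensitivity — but deliberately does not model the *mechanisms* of response bias:
errors are uniform random replacements, not confusion-matrix or
adjacent-category errors (see Limitations).

## Response-error model

Each bias-susceptible categorical feature χ has a finite answer set *A*. Cells
are selected independently (across rows and features) with probability *p*; a
selected response is replaced by a uniform draw from *A*. Two replacement
semantics exist because natural-language descriptions of "replacing an answer"
are ambiguous about whether the original answer may be redrawn:

- `exclude_original = False` (default): the draw covers all of *A*; the
  probability a selected cell changes value is `1 − 1/|A|`, so the effective
  per-cell change rate is `p·(1 − 1/|A|)` (`expected_change_rate` gives the
  closed form).
- `exclude_original = True`: the draw covers `A \ {r}`, so every selected cell
  changes and the change rate is exactly *p*.

The default follows the displayed replacement rule; the exclusive reading is one
flag away. Randomness: a single seed deterministically derives one substream per
feature (via a CRC of the feature name), so adding a feature to the target set
never alters the draws for other features, and single-feature perturbation is
exactly the restriction of all-feature perturbation.

Missing cells behave like any other cell: if selected, they receive a valid
uniform draw. Tests of the analytic change rate therefore use cohorts generated
without missingness.

## Synthetic cohort generator

The generator emulates the structure of a one-shot undergraduate health-survey
dataset (n = 4184 by default). What it reproduces:

- the 17 bias-susceptible survey items with their bias categories (6 subjective
  interpretation, 8 memory recall, 3 health-related) and printed answer-set
  cardinalities where stated (e.g. the 5-level smoking item); items whose
  cardinality is not stated default to binary yes/no;
- demographic marginals: gender (57.4% / 42.6%), age bands (5/36/28/31%);
- biometric and contextual covariates (diastolic blood pressure, heart rate,
  height, weight, parental home, field of study, vaccination status, need for a
  control examination) with plausible locations and scales (e.g. diastolic BP
  72 ± 10 mmHg, heart rate 74 ± 11 bpm);
- outcome prevalences of 12% (MDD) and 8% (GAD).

Covariates are sampled **independently** per feature. Outcomes follow a logistic
link: `logit P(y=1|x) = β0 + Σ βj·zj`, with `zj` the standardized value of a
continuous feature or the centered integer code of a categorical one. β0 is
calibrated by deterministic scalar root-finding (Brent's method on
`mean(expit(β0 + η)) − target` over the sampled covariates, bracket ±60) rather
than rejection sampling, for reproducibility and speed; given the sampled
covariates, the expected prevalence equals the target essentially exactly, so
the realized prevalence is binomial around it.

Default effect sizes are nonzero for a documented subset (MDD loads on financial
difficulties, junk food, drinking, smoking, diastolic BP, parental home,
vaccination; GAD on gender, meal irregularity, binge drinking, physical
activity, heart rate, height, control examination), with magnitudes 0.25–0.6 on
the log-odds scale — enough to make default cohorts learnable (logistic
cross-validated AUC ≈ 0.62 at n = 4184) without being unrealistically separable.

A `missing_rate` fraction of feature cells (default 0.02) is masked after labels
are drawn, so downstream imputation is exercised; outcomes are never masked, and
marginal summaries compute categorical frequencies over observed cells only, so
they remain unbiased under masking.

**What the generator does not emulate:** covariate correlations (real survey
items are strongly inter-correlated — the two smoking items here are sampled
independently, which no real cohort would show), non-logistic outcome
mechanisms, informative missingness, and any real joint distribution of the
source dataset. Passing tests on synthetic cohorts therefore demonstrate that
the *protocol* behaves correctly (degradation when signal-bearing features are
corrupted, no degradation at p = 0, correct calibration), not that any model's
real-data performance is reproduced.

## Metrics and composite score

All metrics are computed from first principles (confusion counts, ranks) and are
cross-checked in the test suite against independent brute-force oracles and
scikit-learn: accuracy, recall, positive/negative precision, binary F1,
support-weighted F1, Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)`, error rate
(`1 − accuracy` by construction), binary cross-entropy with probabilities
clipped to `[1e-15, 1 − 1e-15]`, and ROC AUC as the tie-adjusted normalized
Mann–Whitney U. Zero-denominator ratios return 0 with a logged warning — the
convention under which a model that never predicts positives reports positive
precision 0.0 rather than NaN, matching how such results are conventionally
tabulated.

The composite model-selection score is `CS = w1·AUC + w2·κ·H(R)` with defaults
`w1 = 2, w2 = 0.25`. Two parses of the gated product are possible (`H(R)·κ` vs
`H(κ)·R`); the recall-gated form is the default because the step function is
defined on the non-negative domain that recall occupies, and the alternative is
available via `gate="kappa"`. H is extended as 0 for negative arguments (moot
for recall). Fold-averaged ROC curves use vertical averaging on a fixed 101-point
FPR grid; the reported mean AUC is the mean of per-fold AUCs, not the AUC of the
averaged curve (the averaged curve is for display only).

## Classifier families

Tree, boosting, linear and Bayes families delegate to scikit-learn / xgboost
behind a uniform fit/predict-probabilities adapter. Defaults are the
ablation-selected configurations: random forest (balanced class weight, 1000
trees, depth 12, min split 12, min leaf 10); XGBoost (binary logistic, 50
estimators, depth 7, learning rate 1e-4, gamma 0, alpha 2.5, column subsample
0.2 — the tiny learning rate is reproduced verbatim from the selected
configuration and makes the booster's scores nearly constant, which is faithful
rather than a defect of this package); logistic regression (100 iterations, L2,
C = 10, no intercept, balanced class weight, Newton-CG — trained on
training-fold-standardized inputs, since a no-intercept linear model on raw
columns with nonzero means is not meaningful); Gaussian naive Bayes (variance
smoothing 1e-4).

The 1-D convolutional network is a compact numpy implementation (no deep-learning
framework dependency): each row is a length-F single-channel sequence in schema
column order → Conv1D(64 filters, kernel 3, ReLU, valid padding) → max-pool(2)
→ dropout(0.5) → flatten → dense(50, ReLU) → dense(1, sigmoid), binary
cross-entropy, Adam (lr 1e-3, β1 0.9, β2 0.999, ε 1e-8), batch size 16. At
F ≈ 27 this is ~4×10⁴ parameters. The epoch count is configurable (default 100)
because the protocol selects parameters by callback rather than by a fixed
stopping point: after every epoch the composite score is computed on the
validation set at threshold 0.5, and the parameters of the best epoch are
restored into the returned handle (so the restored model's validation composite
always equals the recorded maximum). A single-class validation set makes AUC
undefined; the callback then falls back to minimum-training-loss selection with
a warning. Training is fully deterministic given the spec seed (numpy only).

SMOTE (in-repo: k = 5 nearest minority neighbors via scikit-learn
`NearestNeighbors`, synthetic rows as convex combinations) balances the classes
on the **training fold only** for the convolutional path by default. Applying it
before the train/validation split — as the original protocol describes — leaks
synthetic copies of validation neighbors into training; that variant exists
behind `paper_faithful` flags but is not the default. If the minority class has
≤ k members, k is reduced with a warning; a singleton minority is an error.

## Cross-validation protocol

10-fold cross-validation, stratified by default: at 8–12% prevalence,
unstratified folds of a few hundred rows are occasionally single-class, which
makes several metrics degenerate; stratification is switchable off. Encoding
(sorted answer-set label order, for run-to-run stability) and mean imputation
are fit on training rows only and applied to validation rows; a
`paper_faithful_preprocess` flag reproduces whole-dataset preprocessing.
Perturbation is applied once to the whole table before CV (matching how a biased
dataset would be constructed); a per-fold redraw mode exists for variance
studies. Both arms of a robustness comparison share fold assignments (asserted
via a fold fingerprint) and model seeds, so arm differences are attributable to
the perturbation alone. Failed folds (e.g. a model error on a degenerate fold)
are dropped from aggregates with a logged warning. Aggregates report per-metric
mean and sample standard deviation (ddof = 1) over completed folds.

Feature importance uses SHAP mean-|attribution| when that optional backend is
importable, and otherwise permutation importance (mean AUC drop over 10 seeded
shuffles per column) computed in-repo.

## Numerical and design choices

- Probability threshold for hard labels is 0.5 everywhere, including inside the
  callback.
- Cross-entropy clipping ε = 1e-15 keeps the loss finite for saturated scores.
- Kappa returns 0 when chance agreement p_e = 1 (degenerate marginals).
- Intercept calibration tolerance: Brent xtol 1e-12; bracket failure raises a
  calibration error naming the outcome.
- Generator, perturbation and folds all derive per-component substreams from a
  single master seed; equal inputs give bit-identical outputs for everything
  except wall-clock timing columns, which are reported but never asserted.
- Problem sizes used by the test suite and the acceptance script — 50,000-row
  cohorts for marginal checks, 100,000 for rate checks, 5,000 for robustness
  properties, 500 rows / 20 epochs for the network's callback check — were
  chosen so that 3-standard-error binomial bands are decisive while the whole
  suite stays desk-scale on one CPU.

## Limitations

- Uniform replacement is the only error model; no social-desirability-directed
  or adjacent-category errors.
- Independent covariates mean feature-importance and sensitivity rankings on
  synthetic cohorts reflect the planted effects, not realistic confounding.
- The binary outcomes are modeled marginally; MDD/GAD comorbidity is not.
- Real-data results require supplying the original cohort CSV via `--cohort`;
  nothing in the test suite depends on it.
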