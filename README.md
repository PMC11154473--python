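# survbias

Robustness evaluation of machine-learning classifiers that predict **Major
Depressive Disorder (MDD)** and **Generalized Anxiety Disorder (GAD)** from
self-reported survey data, under simulated **subjective response errors**.

Self-reported survey answers are noisy: respondents misremember habits, interpret
questions differently, and under-report stigmatized behaviors. A classifier that
looks accurate on clean survey data may degrade sharply once such errors appear.
`survbias` packages the full evaluation protocol for studying this: a synthetic
cohort generator, a probabilistic response-error simulator, a multi-metric
evaluation suite with a composite model-selection score, adapters over five
classifier families, and a paired original-vs-perturbed cross-validation harness
with per-feature sensitivity analysis. It is aimed at biostatisticians and
ML-in-health researchers who need to quantify, not assume, classifier stability.

## The model

**Response-error simulator.** For each bias-susceptible categorical survey
feature χ with answer set *A*, every response *r* is independently replaced with
probability *p* (default 0.2) by *U(A)*, a uniform draw from *A*:

```
r' = r     with probability 1 − p
     U(A)  with probability p
```

With the original answer included in the draw, the probability a selected cell
actually changes is `p·(1 − 1/|A|)`; an `exclude_original` mode draws from
*A \ {r}* instead, forcing every selected answer to change.

**Composite score.** Model selection uses a single statistic combining
discrimination, chance-corrected agreement, and sensitivity:

```
CS = w1·AUC + w2·κ·H(R)
```

where κ is Cohen's kappa, *R* is recall, *H* is the Heaviside step
(`H(x) = 1 if x > 0 else 0`), and the default weights are `w1 = 2`, `w2 = 0.25`.
A model that never recovers a true positive gets no credit for its agreement term.

**Synthetic cohorts.** The generator emulates a cross-sectional undergraduate
mental-health survey of n = 4184 participants: 17 bias-susceptible survey items
(subjective interpretation, memory recall, and health-related bias categories),
demographics with the study's marginals (57.4% female; age bands at 5/36/28/31%),
and biometric/contextual covariates (diastolic blood pressure, heart rate, height,
weight, parental home, field of study, ...). Outcome labels follow a logistic
model whose intercept is calibrated by root-finding so marginal prevalences hit
their targets (12% MDD, 8% GAD).

**Classifier families.** XGBoost, random forest, logistic regression, Gaussian
naive Bayes (via scikit-learn / xgboost), and a compact 1-D convolutional network
(implemented in numpy: conv → max-pool → dropout → flatten → dense → sigmoid,
Adam, binary cross-entropy) with SMOTE minority oversampling and an epoch-level
callback that restores the parameters maximizing CS on the validation fold.

## Worked example

```python
import survbias as sb

schema = sb.build_default_schema()
table = sb.generate_cohort(schema, n=4184, seed=1)

report = sb.compare_robustness(
    [sb.default_spec("logistic", seed=1)],
    table, "MDD",
    sb.PerturbationConfig(p=0.2, seed=1),
    sb.CVPlan(k=10, seed=1),
)
res = report.results["logistic"]
print(f"original  AUC {res['original']['auc']['mean']:.3f} ± {res['original']['auc']['sd']:.3f}")
print(f"perturbed AUC {res['perturbed']['auc']['mean']:.3f} ± {res['perturbed']['auc']['sd']:.3f}")
```

prints (means ± sd over the 10 folds):

```
original  AUC 0.621 ± 0.059
perturbed AUC 0.607 ± 0.058
```

i.e. injecting a 0.2-probability uniform response error into the 17
bias-susceptible items costs the logistic model about 0.014 AUC on this cohort —
the signal carried by the noisy survey items is partially destroyed, while the
biometric covariates keep discrimination above chance.

The same workflow is available from the shell:

```bash
survbias generate --n 4184 --seed 1 --out cohort.csv --schema-out schema.yaml
survbias perturb --in cohort.csv --schema schema.yaml --p 0.2 --seed 1 \
    --out perturbed.csv --log perturb_log.csv
survbias evaluate --cohort cohort.csv --schema schema.yaml --outcome MDD \
    --models logistic,naive_bayes --out results/
```

Per-feature sensitivity (which single survey item hurts most when corrupted) is
`sb.feature_sensitivity(...)`, returning perturbed-minus-original deltas of AUC,
recall, positive precision, and Cohen's kappa for each of the 17 items.

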