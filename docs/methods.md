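# Methods

## The prediction procedure

`simpredict` treats outcome prediction as an instance-based, per-patient
problem. Given a complete-case cohort (one row per ICU admission, each
admission treated as an independent "patient") and an index patient whose
outcome is unknown, it

1. computes the cosine patient-similarity metric (PSM) between the index
   patient and every training patient,
2. sorts training patients by descending PSM (ties broken by ascending
   patient id, so results are reproducible and seed-independent),
3. trains a model on only the N most similar patients, and
4. emits the model's risk for the index patient, a number in [0, 1].

Under stratified k-fold cross-validation (default k = 10), every patient
serves as an index patient exactly once, each fold's predictions are pooled,
and AUROC/AUPRC are computed per fold, giving k values per metric per N.

### The similarity metric

Continuous predictors are rescaled linearly so the reference cohort's minimum
maps to −1 and maximum to +1; this keeps every predictor on an equal footing
in the dot product. Values outside the fitted range (possible when the scaler
is fitted on a training fold and applied to test patients) are clipped to ±1
rather than extrapolated, preserving that equal-contribution rationale.
Constant features carry no similarity information and map to 0 (logged once).

Categorical dimensions enter all-or-none: the product term is +1 for a
matching category and −1 otherwise, and each categorical dimension contributes
exactly 1 to each vector's squared magnitude. That magnitude convention is the
unique one consistent with the ±1 product — a lone matching categorical gives
PSM = 1 and a lone mismatch −1. High-cardinality categoricals (the ICD-9
stand-in) use exact match only; no code-hierarchy similarity is attempted.

By default the scaler is fitted per training fold and applied to the fold's
test patients, which avoids test-set leakage; a global mode
(`--normalize-globally`) fits on the whole dataset instead for users who want
whole-cohort normalization semantics. The two differ only through fold-level
min/max estimates and agree closely at realistic cohort sizes.

Floating-point note: PSM values are clamped to [−1, 1], the categorical sum is
accumulated as an integer before being added to the continuous dot product,
and equal-magnitude pairs divide by the squared magnitude directly, so
PSM(v, v) = 1 and PSM(v, −v) = −1 hold exactly, not just to tolerance.

### Local models

* **Death counting**: risk = deaths among top-N neighbors / N. Valid from
  N = 10 upward.
* **Logistic regression**: ML fit on all schema features with categoricals
  dummy-coded against a fixed reference level (first level in sorted order).
  A small total L2 ridge (1e−6, i.e. practically unpenalized but proof against
  perfect separation in small local subsets) stabilizes the fit; `l2=0`
  requests a strictly unpenalized fit. Categorical levels absent from a local
  subset keep coefficient 0 with a warning; `strict=True` raises instead,
  matching the rationale for a minimum N of 5000 (every level must be
  represented to estimate every coefficient). Unseen levels at prediction
  time map to the reference level.
* **Decision tree**: CART, Gini impurity, maximum depth 8, minimum leaf 20 —
  ordinary CART-scale defaults for training sets of 2,000–15,000; the tree
  hyperparameters are deliberately unexciting because the tree is a
  comparison arm, not the contribution. Leaf risks are Laplace-smoothed,
  (deaths + 1)/(leaf size + 2), so pure leaves never emit hard 0/1 risks;
  raw proportions are available (`smoothed=False`).
* **Minimum N defaults** (10 / 5000 / 2000 for counting / logistic / tree) are
  configuration, not constants; sensible minima depend on the dataset.

If a local training subset contains a single outcome class (possible at the
small end of a grid), the sweep falls back to death counting on that
neighborhood and logs a warning; `fallback="error"` makes it hard-fail.
At N = full training size every index patient's neighborhood is the whole
fold, so the sweep fits one shared model per fold (a pure optimization; the
degenerate-limit test verifies per-index and global predictions coincide).

### Evaluation

* **Folds**: expired and survived patients are permuted independently
  (seeded) and dealt round-robin into k folds; the dealing cursor carries over
  between the two strata, so per-class fold sizes differ by at most one *and*
  total fold sizes stay balanced.
* **AUROC**: Mann–Whitney rank estimator; ties count ½. Equivalent to the
  brute-force mean over all (positive, negative) pairs, which the tests assert.
* **AUPRC**: average precision with tied risks processed as one block — every
  positive in a block is credited the precision at the block's end, and no
  linear interpolation is applied between precision–recall points (PR areas
  are not interpolable the way ROC areas are). Under this convention a
  constant classifier scores exactly the prevalence.
* **Summaries**: per-N fold values are reported as mean ± t_{k−1,0.975}·sd/√k.
  The t-based interval is a choice; with k = 10 it is the standard small-sample
  construction. Constant fold values give a zero-width interval exactly.
* **Comparisons**: two-sided two-sample t-tests at α = 0.05, Welch by default
  (pooled-variance mode available); degenerate zero-variance pairs return
  p = 1 for equal means. Peak-vs-benchmark and peak-vs-max-N comparisons use
  unpaired tests on fold values from the same fold assignment. No
  multiple-testing correction is applied.
* **Severity-score benchmarks** are customized by univariable logistic
  regression of the outcome on the raw score over the *entire* training fold
  (not a similar-patient subset). With a positive fitted slope this is a
  strictly monotone transform, so it cannot change AUROC — customization
  matters for calibration, not discrimination, which the tests assert.

## The synthetic-data generator

Real first-day ICU data at scale are access-restricted, so the package
generates cohorts that reproduce the *statistical shape* the method cares
about rather than clinical physiology:

* ~70 continuous predictors named and scaled like first-day worst-value
  extraction (min/max of 6 vitals over four 6-hour windows, min/max of 8
  labs, age, minimum GCS, four urine outputs), with max = min + positive
  noise so the near-collinearity of worst-value pairs is exercised; values
  are clipped to plausible unit ranges.
* categoricals (admission type 3 levels, gender 2, service 4, ICD-9 stand-in
  with 40 Zipf-distributed levels, vasopressor, ventilation) drawn from
  per-cluster multinomials.
* 6 latent clusters (mildly imbalanced) whose continuous means sit at
  orthogonal directions with separation norm 0 / 3.5 / 7 in the standardized
  latent space for `cluster_effect` none / moderate / high.
* true risk = logistic(α_c + β_cᵀ x_std) with *cluster-specific* coefficient
  vectors: identical across clusters under `none`, orthogonal (disjoint
  feature blocks, ‖β‖ = 1.8) under `high`, mixed halfway under `moderate`.
  Cluster-specific slopes — not merely shifted intercepts — are what make a
  local model class genuinely beat a global one; with intercept shifts alone
  a single global logit could absorb the structure.
* a global intercept shift found by bisection sets the mean true risk to the
  prevalence target (default 0.151, a typical 30-day ICU mortality rate);
  outcomes are independent Bernoulli draws from the true risk.
* synthetic SAPS-like and SOFA-like scores are noisy monotone transforms of
  the true risk; the noise scale is found by bisection so each score's
  in-sample AUROC hits its target (defaults 0.66 and 0.63, the discrimination
  range typical of customized first-day severity scores). Targets above what
  the true risk itself can discriminate raise a config error.

Ground truth (cluster labels, true risks, generating coefficients) is emitted
alongside the cohort and consumed only by tests — never by the pipeline.

What passing tests on these cohorts do and do not show: they demonstrate that
the pipeline detects locality when subgroup-specific risk mechanisms exist and
reports none when they do not; they do not demonstrate that any particular
real ICU population has such structure, nor emulate real joint distributions,
missingness patterns, or repeated admissions by the same patient.

## Problem sizes

The sweep caches one similarity ranking per (index patient, fold) and reuses
it across the entire N grid; death-counting risks for all N come from one
cumulative sum over each index patient's outcome-sorted neighbors. A
4,000-patient cohort with a 50-point grid under 5-fold CV therefore runs in a
couple of seconds. The simulation-based tests use 4,000-patient cohorts with
5 folds and 20 seeds for the trade-off and null-control checks, and 400–2,000
patients elsewhere — sizes at which the checked effects are comfortably
resolved while the full suite stays fast. Logistic/tree sweeps at
intermediate N refit one model per index patient and are the expensive path;
the degenerate limit N = |train| uses the shared-fit fast path.

## Known limitations

* Complete-case analysis only; no imputation (by design, matching the
  framework's inclusion rule).
* No approximate nearest-neighbor index: similarity is exact and O(n²) per
  fold, fine at 10⁴–10⁵ patients, not at 10⁷.
* The PSM weights all predictors equally after rescaling; no learned metric.
* Unpaired t-tests on fold values ignore the pairing across conditions that
  share a fold assignment and are therefore conservative.
* The generator's clusters are axis-orthogonal Gaussians — a deliberately
  idealized geometry for testing, not a claim about case-mix structure.
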