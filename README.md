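# simpredict

Personalized mortality prediction from similar-patient cohorts.

Severity-of-illness scores and other one-size-fits-all prognostic models are
fitted to large heterogeneous populations: they do well for the average ICU
patient and worse for patients far from that average. `simpredict` implements
the instance-based alternative: for each *index patient*, find the N past
patients most similar to them, train a small custom model on only those
neighbors, and predict the index patient's 30-day mortality risk from it. The
package is aimed at clinical-informatics researchers who want to study the
resulting trade-off — small N gives homogeneous but noisy training data, large
N gives stable but diluted training data — on their own cohort tables or on
the bundled synthetic ICU-like cohorts.

## The method

Each patient is a vector **P** of first-day predictors: continuous values
(worst vitals and labs, age, minimum GCS, urine outputs) rescaled to [−1, 1],
plus categorical values (admission type, gender, ICU service, primary ICD-9
code, vasopressor use, ventilation). Similarity between two patients is the
cosine of the angle between their vectors,

```
PSM(P1, P2) = P1 · P2 / (‖P1‖ ‖P2‖),
```

where each categorical dimension contributes +1 to the dot product when the
categories match and −1 otherwise (all-or-none), and exactly 1 to each
vector's squared magnitude. PSM ∈ [−1, 1]: identical vectors score 1,
opposite continuous vectors score −1.

For every index patient in a test fold, the package ranks all training
patients by descending PSM, keeps the top N, and fits one of three local
models on them:

* **death counting** — predicted risk = observed mortality rate among the N
  neighbors;
* **logistic regression** — ML logit on all features (dummy-coded
  categoricals, tiny L2 ridge for near-separable local subsets);
* **decision tree** — CART with Gini impurity and Laplace-smoothed
  (d+1)/(n+2) leaf risks.

Sweeping N under stratified k-fold cross-validation produces, per N, fold-level
AUROC (Mann–Whitney rank form) and AUPRC (average precision with tie blocks,
so a random classifier scores the prevalence, not 0.5), summarized as a mean
with a t-based 95% CI. Benchmarks are logit-customized severity scores
(`logit(risk) = α + β·score`, refitted on each training fold), and
the peak of the sweep is compared against the maximum-N condition and each
benchmark with two-sided two-sample t-tests (α = 0.05).

Because real critical-care databases are access-restricted, the package ships
a synthetic-cohort generator with latent patient subgroups and
subgroup-specific risk mechanisms, plus ground truth for recovery tests (see
`docs/methods.md`).

## Worked example

```sh
simpredict generate --n 4000 --seed 1 --out cohort.csv \
    --schema-out schema.json --truth-out truth.tsv
simpredict sweep --cohort cohort.csv --schema schema.json \
    --model death_count --n-grid 10:500:10 --k 5 --seed 1 --out results
simpredict benchmark --cohort cohort.csv --schema schema.json \
    --k 5 --seed 1 --out results
simpredict report --in results
```

prints

```
generated 4000 patients (prevalence 0.153) -> cohort.csv
AUROC: peak mean 0.748 [0.725, 0.771] at N=270
AUPRC: peak mean 0.381 [0.342, 0.419] at N=270
saps AUROC: 0.664 [0.645, 0.682]
saps AUPRC: 0.280 [0.240, 0.320]
sofa AUROC: 0.627 [0.595, 0.659]
sofa AUPRC: 0.234 [0.219, 0.250]
```

Reading the numbers: on this 4,000-patient clustered synthetic cohort, death
counting among the 270 most similar patients discriminates 30-day mortality
with mean AUROC 0.748 across the 5 folds — better than using all 500
neighbors on the grid's right edge (0.738) and clearly better than the
customized SAPS-like (0.664) and SOFA-like (0.627) benchmark scores. The peak
at an *intermediate* N is the homogeneity-vs-sample-size trade-off the package
exists to expose; `results/sweep_death_count.tsv` holds the full per-N table
(mean, 95% CI and per-fold values), `comparisons_death_count.tsv` the peak
t-tests, and `sweep_death_count.png` the trade-off curves.

The same works from Python:

```python
from simpredict import GeneratorConfig, SweepConfig, generate_cohort, run_sweep, find_peak

cohort = generate_cohort(GeneratorConfig(n_patients=4000, seed=1)).cohort
result = run_sweep(cohort, SweepConfig("death_count", tuple(range(10, 501, 10)),
                                       k_folds=5, seed=1))
n_star, peak = find_peak(result, "AUROC")
```

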