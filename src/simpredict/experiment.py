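"""Orchestration: the per-index-patient prediction loop and the N-sweep.

For each test (index) patient within a stratified cross-validation fold:

1. compute all pairwise PSM values between the index patient and every
   training patient;
2. sort training patients by descending PSM (ties by ascending patient id);
3. train the chosen model on only the N most similar patients;
4. predict the index patient's mortality risk.

The sweep repeats this for every N in a grid, reusing one cached similarity
ranking per index patient across the whole grid (the dominant cost), and
summarizes fold-level AUROC/AUPRC as mean with 95% CI per N — plus peak
identification and t-test comparisons against the maximum-N condition and
customized severity-score benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .evaluation import (
    AUPRC,
    AUROC,
    FoldAssignment,
    MetricSummary,
    auprc,
    auroc,
    compare_fold_metrics,
    mean_ci,
    stratified_folds,
)
from .predictors import (
    DEATH_COUNT,
    LOGISTIC,
    MIN_N_DEFAULTS,
    MODEL_KINDS,
    TREE,
    DesignEncoder,
    RiskPrediction,
    SingleClassError,
    _fit_logistic_matrix,
    _fit_tree_matrix,
    customize_soi,
)
from .similarity import encode_categoricals, fit_scaler, similarity_matrix

log = logging.getLogger("simpredict")

PER_FOLD = "per_fold"
GLOBAL = "global"


class ConfigError(ValueError):
    """Sweep configuration is infeasible for the given cohort."""


@dataclass(frozen=True)
class SweepConfig:
    model_kind: str
    n_grid: tuple
    k_folds: int = 10
    seed: int = 0
    normalization_mode: str = PER_FOLD
    minimum_n: int | None = None
    fallback: str = "death_count"  # or "error"

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ConfigError(f"unknown model kind {self.model_kind!r}")
        object.__setattr__(self, "n_grid", tuple(int(n) for n in self.n_grid))
        if not self.n_grid:
            raise ConfigError("n_grid is empty")
        if any(b <= a for a, b in zip(self.n_grid, self.n_grid[1:])):
            raise ConfigError("n_grid must be strictly increasing")
        if self.minimum_n is None:
            object.__setattr__(self, "minimum_n", MIN_N_DEFAULTS[self.model_kind])
        if self.n_grid[0] < self.minimum_n:
            raise ConfigError(
                f"smallest N={self.n_grid[0]} is below minimum_n="
                f"{self.minimum_n} for model {self.model_kind!r}"
            )
        if self.normalization_mode not in (PER_FOLD, GLOBAL):
            raise ConfigError(f"unknown normalization mode {self.normalization_mode!r}")
        if self.fallback not in ("death_count", "error"):
            raise ConfigError(f"unknown fallback policy {self.fallback!r}")


def default_n_grid(model_kind: str, train_size: int) -> tuple:
    """The standard sweep grids: death counting 10..500 step 10; logistic
    5000..train_size step 1000; tree 2000..train_size step 1000 (the training
    set size itself is always included for the latter two)."""
    if model_kind == DEATH_COUNT:
        return tuple(range(10, min(501, train_size + 1), 10))
    start = MIN_N_DEFAULTS[model_kind]
    if train_size < start:
        raise ConfigError(
            f"training size {train_size} below the minimum {start} for {model_kind}"
        )
    grid = list(range(start, train_size + 1, 1000))
    if grid[-1] != train_size:
        grid.append(train_size)
    return tuple(grid)


@dataclass
class SweepResult:
    """Per-N fold-level AUROC/AUPRC with means and 95% CIs."""

    config: SweepConfig
    folds: FoldAssignment
    summaries: dict = field(repr=False)  # metric -> {N: MetricSummary}

    @property
    def n_grid(self) -> tuple:
        return self.config.n_grid

    def summary(self, metric: str, n: int) -> MetricSummary:
        return self.summaries[metric][n]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, by_n in self.summaries.items():
            for n, s in by_n.items():
                row = {
                    "metric": metric,
                    "n_similar": n,
                    "mean": s.mean,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                }
                row.update(
                    {f"fold_{i}": v for i, v in enumerate(s.fold_values, start=1)}
                )
                rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fold preparation
# ---------------------------------------------------------------------------

@dataclass
class _FoldContext:
    train: Cohort
    test: Cohort
    order: np.ndarray  # (n_test, n_train) train positions by descending PSM
    y_train: np.ndarray
    y_test: np.ndarray


def _prepare_fold(
    cohort: Cohort, folds: FoldAssignment, fold: int, normalization_mode: str
) -> _FoldContext:
    mask_test = folds.folds == fold
    train = cohort.iloc_subset(np.flatnonzero(~mask_test))
    test = cohort.iloc_subset(np.flatnonzero(mask_test))
    scaler = fit_scaler(cohort if normalization_mode == GLOBAL else train)
    cont_train = scaler.transform(train.continuous_matrix())
    cont_test = scaler.transform(test.continuous_matrix())
    cat_train, cat_test = encode_categoricals(
        train.categorical_frame(), test.categorical_frame()
    )
    sim = similarity_matrix(cont_test, cat_test, cont_train, cat_train)
    # train columns are in ascending-id order, so a stable sort on -PSM breaks
    # ties by ascending candidate id
    order = np.argsort(-sim, axis=1, kind="stable")
    return _FoldContext(
        train=train,
        test=test,
        order=order,
        y_train=train.outcomes,
        y_test=test.outcomes,
    )


def _fold_risks(
    ctx: _FoldContext, model_kind: str, n_values, fallback: str = "death_count"
):
    """Risks for every test patient at every N in ``n_values`` (dict N -> array)."""
    n_train = len(ctx.y_train)
    for n in n_values:
        if n > n_train:
            raise ConfigError(f"N={n} exceeds training size {n_train}")
    out = {}
    if model_kind == DEATH_COUNT:
        sorted_outcomes = ctx.y_train[ctx.order]
        cums = np.cumsum(sorted_outcomes, axis=1)
        for n in n_values:
            out[n] = cums[:, n - 1] / n
        return out

    encoder = DesignEncoder(ctx.train)
    X_train = encoder.transform(ctx.train.table, warn_unseen=False)
    X_test = encoder.transform(ctx.test.table)
    fit = _fit_logistic_matrix if model_kind == LOGISTIC else _fit_tree_matrix
    for n in n_values:
        if n == n_train:
            # degenerate limit: the neighborhood is the whole training fold,
            # so one shared global fit serves every index patient
            model = fit(encoder, X_train, ctx.y_train)
            out[n] = model.risk_from_design(X_test)
            continue
        risks = np.empty(len(ctx.y_test))
        n_fallback = 0
        for i in range(len(ctx.y_test)):
            idx = ctx.order[i, :n]
            y_sub = ctx.y_train[idx]
            if y_sub.min() == y_sub.max():
                if fallback == "error":
                    raise SingleClassError(
                        f"single-class neighborhood (N={n}) for index patient "
                        f"{ctx.test.ids[i]!r}"
                    )
                risks[i] = float(y_sub.mean())
                n_fallback += 1
                continue
            model = fit(encoder, X_train[idx], y_sub)
            risks[i] = float(model.risk_from_design(X_test[i : i + 1])[0])
        if n_fallback:
            log.warning(
                "N=%d: fell back to death counting for %d of %d index patients "
                "(single-class neighborhood)",
                n, n_fallback, len(ctx.y_test),
            )
        out[n] = risks
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def predict_fold(
    train: Cohort,
    test: Cohort,
    model_kind: str,
    n: int,
    normalization_mode: str = PER_FOLD,
    fallback: str = "death_count",
) -> list[RiskPrediction]:
    """Personalized risk prediction for every test patient from one
    train/test split."""
    if set(train.ids) & set(test.ids):
        raise ValueError("train and test cohorts share patient ids")
    fold_ids = tuple(train.ids) + tuple(test.ids)
    folds = FoldAssignment(
        k=2,
        seed=0,
        ids=fold_ids,
        folds=np.concatenate([np.ones(train.n, int), np.full(test.n, 2, int)]),
    )
    combined = Cohort(train.schema, pd.concat([train.table, test.table]).sort_index())
    ctx = _prepare_fold(combined, _realign(folds, combined), 2, normalization_mode)
    risks = _fold_risks(ctx, model_kind, [n], fallback=fallback)[n]
    return [
        RiskPrediction(pid, float(r), model_kind, n)
        for pid, r in zip(ctx.test.ids, risks)
    ]


def _realign(folds: FoldAssignment, cohort: Cohort) -> FoldAssignment:
    lookup = dict(zip(folds.ids, folds.folds))
    aligned = np.array([lookup[i] for i in cohort.ids], dtype=int)
    return FoldAssignment(k=folds.k, seed=folds.seed, ids=tuple(cohort.ids), folds=aligned)


def run_sweep(cohort: Cohort, config: SweepConfig) -> SweepResult:
    """Run the full N-sweep under one stratified fold assignment.

    Rankings are computed once per (index patient, fold) and reused across the
    entire grid.  Deterministic: identical (cohort, config) pairs produce
    identical results.
    """
    folds = stratified_folds(
        pd.Series(cohort.outcomes, index=list(cohort.ids)), config.k_folds, config.seed
    )
    fold_sizes = np.bincount(folds.folds, minlength=config.k_folds + 1)[1:]
    min_train = cohort.n - int(fold_sizes.max())
    if config.n_grid[-1] > min_train:
        raise ConfigError(
            f"largest N={config.n_grid[-1]} exceeds the smallest training-fold "
            f"size {min_train}"
        )
    fold_values: dict = {AUROC: {n: [] for n in config.n_grid},
                         AUPRC: {n: [] for n in config.n_grid}}
    for fold in range(1, config.k_folds + 1):
        log.info("fold %d/%d: ranking and prediction", fold, config.k_folds)
        ctx = _prepare_fold(cohort, folds, fold, config.normalization_mode)
        risks_by_n = _fold_risks(ctx, config.model_kind, config.n_grid, config.fallback)
        for n in config.n_grid:
            fold_values[AUROC][n].append(auroc(risks_by_n[n], ctx.y_test))
            fold_values[AUPRC][n].append(auprc(risks_by_n[n], ctx.y_test))
    summaries = {
        metric: {
            n: mean_ci(values, metric_name=metric)
            for n, values in by_n.items()
        }
        for metric, by_n in fold_values.items()
    }
    return SweepResult(config=config, folds=folds, summaries=summaries)


def find_peak(result: SweepResult, metric_name: str) -> tuple[int, MetricSummary]:
    """N with the maximal fold-mean of the metric; ties go to the smallest N."""
    by_n = result.summaries[metric_name]
    best_n = None
    best = -np.inf
    for n in result.n_grid:  # ascending, so strict > keeps the smallest tie
        if by_n[n].mean > best:
            best, best_n = by_n[n].mean, n
    return best_n, by_n[best_n]


def run_benchmarks(cohort: Cohort, folds: FoldAssignment) -> dict:
    """Customized severity-score benchmarks on the same fold assignment.

    For each score column and each fold, the score is recalibrated by
    univariable logistic regression on the training fold (all training data,
    not a similar-patient subset) and evaluated on the test fold.
    Returns {score: {metric: MetricSummary}}.
    """
    if not cohort.schema.score_columns:
        raise ValueError("cohort declares no score columns to benchmark")
    aligned = _realign(folds, cohort)
    out = {}
    for column in cohort.schema.score_columns:
        scores = cohort.scores(column)
        y = cohort.outcomes
        roc_values, prc_values = [], []
        for fold in range(1, folds.k + 1):
            mask_test = aligned.folds == fold
            model = customize_soi(scores[~mask_test], y[~mask_test])
            risks = model.predict_risk_values(scores[mask_test])
            roc_values.append(auroc(risks, y[mask_test]))
            prc_values.append(auprc(risks, y[mask_test]))
        out[column] = {
            AUROC: mean_ci(roc_values, metric_name=AUROC),
            AUPRC: mean_ci(prc_values, metric_name=AUPRC),
        }
    return out


def compare_conditions(
    result: SweepResult,
    benchmark_folds: dict | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided t-test comparisons of the sweep's peak against the maximum-N
    condition and (optionally) each customized benchmark.

    ``benchmark_folds`` maps benchmark name -> {metric: fold values} (a
    :func:`run_benchmarks` output works directly).  All fold values must come
    from the same fold assignment (same k).
    """
    rows = []
    k = result.folds.k
    for metric in (AUROC, AUPRC):
        n_star, peak = find_peak(result, metric)
        n_max = result.n_grid[-1]
        p = compare_fold_metrics(peak.fold_values,
                                 result.summary(metric, n_max).fold_values)
        rows.append(
            {
                "metric": metric,
                "comparison": f"peak_vs_N={n_max}",
                "n_peak": n_star,
                "peak_mean": peak.mean,
                "other_mean": result.summary(metric, n_max).mean,
                "p_value": p,
                "significant": p < alpha,
            }
        )
        for name, metrics in (benchmark_folds or {}).items():
            other = metrics[metric]
            values = other.fold_values if isinstance(other, MetricSummary) else tuple(other)
            if len(values) != k:
                raise ValueError(
                    f"benchmark {name!r}: {len(values)} fold values but the "
                    f"sweep used k={k}"
                )
            p = compare_fold_metrics(peak.fold_values, values)
            rows.append(
                {
                    "metric": metric,
                    "comparison": f"peak_vs_{name}",
                    "n_peak": n_star,
                    "peak_mean": peak.mean,
                    "other_mean": float(np.mean(values)),
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)
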