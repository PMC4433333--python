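"""Stratified cross-validation folds and rank-based performance metrics.

AUROC is the Mann–Whitney estimator: the probability that a randomly chosen
expired patient is assigned a higher risk than a randomly chosen survivor,
with ties counting one half.  AUPRC is average precision with tied risks
processed as one block (the block's end precision is credited to all positives
in the block); precision–recall points are never linearly interpolated, so a
constant classifier scores exactly the prevalence rather than 0.5.

Fold assignment is stratified: expired and survived patients are permuted
independently (seeded) and dealt round-robin into k folds with a single dealing
cursor carried across the two strata, so per-class fold sizes differ by at most
one and total fold sizes stay balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AUROC = "AUROC"
AUPRC = "AUPRC"


@dataclass(frozen=True)
class FoldAssignment:
    """Patient id -> fold index in 1..k."""

    k: int
    seed: int
    ids: tuple
    folds: np.ndarray  # int array aligned with ids

    def fold_of(self) -> pd.Series:
        return pd.Series(self.folds, index=list(self.ids))

    def test_ids(self, fold: int) -> np.ndarray:
        return np.asarray(self.ids, dtype=object)[self.folds == fold]

    def train_ids(self, fold: int) -> np.ndarray:
        return np.asarray(self.ids, dtype=object)[self.folds != fold]


def stratified_folds(outcomes: pd.Series, k: int, seed: int) -> FoldAssignment:
    """Assign patients to k folds, stratified by outcome class.

    ``outcomes`` is a binary Series indexed by patient id.  Within each class a
    seeded permutation is dealt round-robin; the dealing cursor continues from
    one class to the next so total fold sizes are as equal as possible.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = outcomes.to_numpy(dtype=int)
    ids = np.asarray(outcomes.index.to_numpy(), dtype=object)
    rng = np.random.default_rng(seed)
    folds = np.zeros(len(ids), dtype=int)
    cursor = 0
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        if len(members) < k:
            raise ValueError(
                f"outcome class {cls} has only {len(members)} members; "
                f"need at least k={k}"
            )
        perm = rng.permutation(members)
        positions = (cursor + np.arange(len(perm))) % k
        folds[perm] = positions + 1
        cursor = (cursor + len(perm)) % k
    return FoldAssignment(k=k, seed=seed, ids=tuple(ids), folds=folds)


def auroc(risks: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUROC with ties counting 1/2."""
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both outcome classes must be present")
    ranks = stats.rankdata(risks)  # average ranks for ties
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auprc(risks: np.ndarray, labels: np.ndarray) -> float:
    """Average precision with tie blocks (no interpolation).

    Risks are processed in descending order; all observations sharing a risk
    value form one block, and every positive in the block is credited the
    precision at the block's end.
    """
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC undefined: at least one positive label required")
    order = np.argsort(-risks, kind="stable")
    r = risks[order]
    y = labels[order]
    # block boundaries: last index of each run of equal risk values
    is_end = np.empty(len(r), dtype=bool)
    is_end[:-1] = r[:-1] != r[1:]
    is_end[-1] = True
    ends = np.flatnonzero(is_end)
    cum_tp = np.cumsum(y)
    tp_at_end = cum_tp[ends]
    prec_at_end = tp_at_end / (ends + 1.0)
    tp_in_block = np.diff(np.concatenate(([0], tp_at_end)))
    return float(np.sum(tp_in_block * prec_at_end) / n_pos)


@dataclass(frozen=True)
class MetricSummary:
    metric_name: str
    fold_values: tuple
    mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("confidence interval does not bracket the mean")


def mean_ci(fold_values, level: float = 0.95, metric_name: str = "metric") -> MetricSummary:
    """Mean of fold-level metric values with a t-based confidence interval:
    mean ± t_{k-1, (1+level)/2} · sd / sqrt(k)."""
    values = np.asarray(fold_values, dtype=float)
    k = len(values)
    if k < 2:
        raise ValueError("need at least 2 fold values for a confidence interval")
    if np.all(values == values[0]):  # constant folds: zero-width interval
        c = float(values[0])
        return MetricSummary(metric_name, tuple(values.tolist()), c, c, c)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = float(stats.t.ppf(0.5 + level / 2.0, df=k - 1)) * sd / np.sqrt(k)
    return MetricSummary(
        metric_name=metric_name,
        fold_values=tuple(values.tolist()),
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
    )


def compare_fold_metrics(values_a, values_b, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value between two sets of fold values.

    Welch by default; set ``equal_var=True`` for the pooled-variance test.
    Degenerate zero-variance inputs: p = 1 when the means agree, p = 0 when
    they differ.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    result = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(result.pvalue)
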