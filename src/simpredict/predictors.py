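"""Local (per-index-patient) risk models and severity-score customization.

Three model families predict an index patient's 30-day mortality risk from the
N most similar past patients:

* **death counting** — the observed mortality rate among the N neighbors;
* **logistic regression** — maximum-likelihood logit on all schema features
  (dummy-coded categoricals), with a tiny L2 ridge to stabilize near-separable
  local subsets;
* **decision tree** — CART with Gini impurity and Laplace-smoothed leaf
  probabilities.

Severity-of-illness scores (SAPS-like, SOFA-like) are "customized" as
benchmarks by refitting a univariable logistic model of the outcome on the raw
score over the whole training fold (logit recalibration), which preserves the
score's ranking whenever the fitted slope is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .cohort import Cohort, SchemaError
from .similarity import SimilarityRanking

log = logging.getLogger("simpredict")

DEATH_COUNT = "death_count"
LOGISTIC = "logistic"
TREE = "tree"
MODEL_KINDS = (DEATH_COUNT, LOGISTIC, TREE)

#: Default minimum neighborhood sizes.  Logistic regression needs every
#: categorical level represented to estimate all coefficients; trees need
#: outcome variability.  These are configuration, not constants: sensible
#: minima change with the dataset and predictors.
MIN_N_DEFAULTS = {DEATH_COUNT: 10, TREE: 2000, LOGISTIC: 5000}


class SingleClassError(ValueError):
    """Training subset contains only one outcome class."""


@dataclass(frozen=True)
class NeighborhoodConfig:
    model_kind: str
    n_similar: int
    minimum_n: int | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.minimum_n is None:
            object.__setattr__(self, "minimum_n", MIN_N_DEFAULTS[self.model_kind])
        if self.minimum_n < 1 or self.n_similar < 1:
            raise ValueError("n_similar and minimum_n must be positive")
        if self.n_similar < self.minimum_n:
            raise ValueError(
                f"n_similar={self.n_similar} is below the minimum of "
                f"{self.minimum_n} for model {self.model_kind!r}"
            )


@dataclass(frozen=True)
class RiskPrediction:
    patient_id: object
    risk: float
    model_kind: str
    n_similar_used: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.risk <= 1.0):
            raise ValueError(f"risk {self.risk} outside [0, 1]")


# ---------------------------------------------------------------------------
# Death counting
# ---------------------------------------------------------------------------

def death_count_risk(
    ranking: SimilarityRanking, outcomes: Mapping, n: int
) -> RiskPrediction:
    """Mortality rate among the index patient's top-n ranked neighbors."""
    if n < 1:
        raise ValueError("n must be >= 1")
    top = ranking.top_ids(n)  # raises if n exceeds ranking length
    deaths = sum(int(outcomes[cid]) for cid in top)
    return RiskPrediction(ranking.index_id, deaths / n, DEATH_COUNT, n)


# ---------------------------------------------------------------------------
# Design-matrix encoding shared by logistic regression and trees
# ---------------------------------------------------------------------------

class DesignEncoder:
    """Maps cohort rows to a numeric design matrix with a fixed column set.

    Continuous features pass through in native units; each categorical feature
    is dummy-coded against a fixed reference level (the first level in sorted
    order among the levels seen when the encoder was fitted).  Levels unseen at
    fit time encode as the reference level (all dummies zero) with a warning —
    per-index training subsets routinely miss rare levels such as uncommon
    ICD-9 codes.
    """

    def __init__(self, cohort: Cohort):
        self.schema = cohort.schema
        self.levels: dict[str, list] = {}
        for col in self.schema.categorical_features:
            self.levels[col] = sorted(cohort.table[col].unique().tolist())
        self.columns: list[str] = list(self.schema.continuous_features)
        for col in self.schema.categorical_features:
            # reference level = first in sorted order
            self.columns += [f"{col}={lv}" for lv in self.levels[col][1:]]

    def transform(self, table: pd.DataFrame, warn_unseen: bool = True) -> np.ndarray:
        n = len(table)
        X = np.zeros((n, len(self.columns)))
        n_cont = len(self.schema.continuous_features)
        if n_cont:
            X[:, :n_cont] = table[list(self.schema.continuous_features)].to_numpy(float)
        j = n_cont
        for col in self.schema.categorical_features:
            values = table[col].to_numpy()
            known = set(self.levels[col])
            if warn_unseen:
                unseen = {v for v in values if v not in known}
                if unseen:
                    log.warning(
                        "feature %r: unseen level(s) %s mapped to reference level",
                        col,
                        sorted(unseen)[:5],
                    )
            for lv in self.levels[col][1:]:
                X[:, j] = values == lv
                j += 1
        return X


def _check_two_classes(y: np.ndarray, context: str) -> None:
    if len(np.unique(y)) < 2:
        raise SingleClassError(
            f"{context}: training subset has a single outcome class; "
            "use a larger neighborhood N or fall back to death counting"
        )


# ---------------------------------------------------------------------------
# Local logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LocalLogisticModel:
    encoder: DesignEncoder
    intercept: float
    coefficients: np.ndarray  # aligned with encoder.columns

    def predict_risk_values(self, table: pd.DataFrame) -> np.ndarray:
        return self.risk_from_design(self.encoder.transform(table))

    def risk_from_design(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + X @ self.coefficients)

    def to_dict(self) -> dict:
        return {
            "kind": LOGISTIC,
            "intercept": self.intercept,
            "coefficients": dict(zip(self.encoder.columns, self.coefficients.tolist())),
        }


def fit_local_logistic(
    subset: Cohort,
    *,
    encoder: DesignEncoder | None = None,
    l2: float = 1e-6,
    strict: bool = False,
) -> LocalLogisticModel:
    """Fit a maximum-likelihood logistic model on a similar-patient subset.

    ``l2`` is a small total ridge penalty stabilizing near-separable local
    fits; set it to 0 for a strictly unpenalized fit.  With ``strict=True``,
    categorical levels absent from the subset raise instead of receiving a
    zero coefficient.
    """
    encoder = encoder or DesignEncoder(subset)
    y = subset.outcomes
    _check_two_classes(y, "logistic regression")
    absent = _absent_levels(subset, encoder)
    if absent:
        msg = f"categorical level(s) absent from training subset: {absent[:5]}"
        if strict:
            raise ValueError(msg)
        log.warning("%s; their coefficients are fixed at 0", msg)
    X = encoder.transform(subset.table, warn_unseen=False)
    return _fit_logistic_matrix(encoder, X, y, l2=l2)


def _absent_levels(subset: Cohort, encoder: DesignEncoder) -> list[str]:
    absent = []
    for col in encoder.schema.categorical_features:
        present = set(subset.table[col].unique())
        absent += [f"{col}={lv}" for lv in encoder.levels[col] if lv not in present]
    return absent


def _fit_logistic_matrix(
    encoder: DesignEncoder, X: np.ndarray, y: np.ndarray, l2: float = 1e-6
) -> LocalLogisticModel:
    C = 1e12 if l2 <= 0 else 1.0 / l2
    clf = LogisticRegression(
        C=C, solver="lbfgs", max_iter=5000, tol=1e-10
    )
    clf.fit(X, y)
    return LocalLogisticModel(encoder, float(clf.intercept_[0]), clf.coef_[0].copy())


# ---------------------------------------------------------------------------
# Local decision tree
# ---------------------------------------------------------------------------

@dataclass
class LocalTreeModel:
    encoder: DesignEncoder
    tree: DecisionTreeClassifier
    smoothed: bool = True

    def predict_risk_values(self, table: pd.DataFrame) -> np.ndarray:
        return self.risk_from_design(self.encoder.transform(table))

    def risk_from_design(self, X: np.ndarray) -> np.ndarray:
        t = self.tree.tree_
        leaves = self.tree.apply(X)
        pos_idx = int(np.where(self.tree.classes_ == 1)[0][0])
        n_leaf = t.weighted_n_node_samples[leaves]
        # tree_.value stores per-node class proportions; recover death counts
        deaths = t.value[leaves, 0, pos_idx] * n_leaf
        if self.smoothed:
            return (deaths + 1.0) / (n_leaf + 2.0)
        return deaths / n_leaf

    def to_dict(self) -> dict:
        t = self.tree.tree_
        return {
            "kind": TREE,
            "n_nodes": int(t.node_count),
            "max_depth": int(self.tree.get_depth()),
            "feature": [
                self.encoder.columns[f] if f >= 0 else None for f in t.feature
            ],
            "threshold": t.threshold.tolist(),
        }


def fit_local_tree(
    subset: Cohort,
    *,
    encoder: DesignEncoder | None = None,
    max_depth: int = 8,
    min_leaf: int = 20,
    smoothed: bool = True,
) -> LocalTreeModel:
    """Fit a CART classification tree (Gini) on a similar-patient subset.

    Leaf risks are Laplace-smoothed proportions (deaths+1)/(size+2) by
    default, which avoids hard 0/1 risks from pure leaves.
    """
    encoder = encoder or DesignEncoder(subset)
    y = subset.outcomes
    _check_two_classes(y, "decision tree")
    X = encoder.transform(subset.table, warn_unseen=False)
    return _fit_tree_matrix(
        encoder, X, y, max_depth=max_depth, min_leaf=min_leaf, smoothed=smoothed
    )


def _fit_tree_matrix(
    encoder: DesignEncoder,
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int = 8,
    min_leaf: int = 20,
    smoothed: bool = True,
) -> LocalTreeModel:
    clf = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        random_state=0,
    )
    clf.fit(X, y)
    return LocalTreeModel(encoder, clf, smoothed=smoothed)


# ---------------------------------------------------------------------------
# Prediction wrapper
# ---------------------------------------------------------------------------

def predict_risk(model, patients: Cohort | pd.DataFrame, n_similar_used: int = 0):
    """Apply a fitted local model to one or more patients.

    Returns a list of :class:`RiskPrediction`, one per patient row.
    """
    table = patients.table if isinstance(patients, Cohort) else patients
    kind = LOGISTIC if isinstance(model, LocalLogisticModel) else TREE
    risks = model.predict_risk_values(table)
    return [
        RiskPrediction(pid, float(r), kind, n_similar_used)
        for pid, r in zip(table.index, risks)
    ]


# ---------------------------------------------------------------------------
# Severity-score customization (benchmarks)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreModel:
    """Univariable logit recalibration of a severity score:
    logit(risk) = alpha + beta * score."""

    alpha: float
    beta: float

    def predict_risk_values(self, scores: np.ndarray) -> np.ndarray:
        return expit(self.alpha + self.beta * np.asarray(scores, dtype=float))

    def to_dict(self) -> dict:
        return {"kind": "score_logit", "alpha": self.alpha, "beta": self.beta}


def customize_soi(scores: np.ndarray, outcomes: np.ndarray, l2: float = 1e-6) -> ScoreModel:
    """Customize a severity-of-illness score via univariable logistic
    regression of the outcome on the raw score (fit on all training data)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if np.all(scores == scores[0]):
        raise ValueError("score column is constant; cannot customize")
    _check_two_classes(y, "score customization")
    C = 1e12 if l2 <= 0 else 1.0 / l2
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(scores.reshape(-1, 1), y)
    return ScoreModel(float(clf.intercept_[0]), float(clf.coef_[0][0]))
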