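"""Cosine patient-similarity metric (PSM) over mixed-type feature vectors.

Each patient is a Euclidean vector: continuous predictors rescaled to [-1, 1]
(so every predictor can contribute equally) concatenated with categorical
predictors handled in an all-or-none fashion.  The PSM between two patients is
the cosine of the angle between their vectors,

    PSM(P1, P2) = P1 . P2 / (||P1|| ||P2||),

where each categorical dimension contributes +1 to the dot product when the two
patients share the category and -1 otherwise, and exactly 1 to each vector's
squared magnitude.  The PSM therefore lies in [-1, 1]: identical vectors score
1, exactly opposite continuous vectors score -1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import Cohort, SchemaError

log = logging.getLogger("simpredict")

_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature min/max recorded from a reference cohort.

    A value equal to ``fitted_min`` maps to -1 and ``fitted_max`` to +1; values
    outside the fitted range are clipped to +/-1.  Features that were constant
    in the reference cohort carry no similarity information and map to 0.
    """

    feature_names: tuple[str, ...]
    fitted_min: np.ndarray
    fitted_max: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if np.any(self.fitted_min > self.fitted_max):
            raise ValueError("fitted_min > fitted_max for some feature")

    @property
    def constant_mask(self) -> np.ndarray:
        return self.fitted_min == self.fitted_max

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Map raw values (n, n_features) or (n_features,) into [-1, 1]."""
        raw = np.asarray(raw, dtype=float)
        span = self.fitted_max - self.fitted_min
        safe_span = np.where(span == 0, 1.0, span)
        scaled = 2.0 * (raw - self.fitted_min) / safe_span - 1.0
        scaled = np.clip(scaled, -1.0, 1.0)
        if raw.ndim == 1:
            scaled = np.where(self.constant_mask, 0.0, scaled)
        else:
            scaled[:, self.constant_mask] = 0.0
        return scaled


def fit_scaler(cohort: Cohort) -> FeatureScaler:
    """Record per-feature min/max of the cohort's continuous predictors."""
    if cohort.n == 0:
        raise ValueError("cannot fit a scaler on an empty cohort")
    names = cohort.schema.continuous_features
    mat = cohort.continuous_matrix()
    mins = mat.min(axis=0) if mat.size else np.empty(0)
    maxs = mat.max(axis=0) if mat.size else np.empty(0)
    n_const = int(np.sum(mins == maxs))
    if n_const:
        log.warning(
            "%d constant continuous feature(s) in reference cohort; "
            "mapped to 0 in all similarity vectors",
            n_const,
        )
    return FeatureScaler(tuple(names), mins, maxs, fitted_on=f"cohort(n={cohort.n})")


def normalize(scaler: FeatureScaler, raw_values: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Normalize one patient's raw continuous values into [-1, 1].

    ``raw_values`` may be a mapping feature name -> value or a sequence in the
    scaler's feature order.
    """
    if isinstance(raw_values, Mapping):
        missing = [f for f in scaler.feature_names if f not in raw_values]
        if missing:
            raise SchemaError(f"feature(s) missing from scaler input: {missing}")
        raw = np.array([raw_values[f] for f in scaler.feature_names], dtype=float)
    else:
        raw = np.asarray(raw_values, dtype=float)
        if raw.shape != (len(scaler.feature_names),):
            raise SchemaError(
                f"expected {len(scaler.feature_names)} values, got {raw.shape}"
            )
    return scaler.transform(raw)


@dataclass(frozen=True)
class PatientVector:
    """One patient's similarity vector: normalized continuous part plus
    opaque categorical labels, in fixed schema order."""

    id: object
    continuous: np.ndarray
    categorical: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "continuous", np.asarray(self.continuous, dtype=float))
        object.__setattr__(self, "categorical", tuple(self.categorical))

    @property
    def squared_magnitude(self) -> float:
        # each categorical dim contributes exactly 1 to the squared magnitude
        return float(self.continuous @ self.continuous) + len(self.categorical)


def psm(p1: PatientVector, p2: PatientVector) -> float:
    """Cosine similarity between two mixed-type patient vectors, in [-1, 1]."""
    if p1.continuous.shape != p2.continuous.shape or len(p1.categorical) != len(p2.categorical):
        raise SchemaError(
            "patient vectors do not conform to the same schema: "
            f"{p1.continuous.shape}/{len(p1.categorical)} vs "
            f"{p2.continuous.shape}/{len(p2.categorical)}"
        )
    # accumulate the categorical +/-1 contributions as an integer so the
    # numerator of two identical vectors is computed by the same operations
    # as the squared magnitude (making PSM(v, v) exactly 1)
    cat_sum = sum(1 if a == b else -1 for a, b in zip(p1.categorical, p2.categorical))
    num = float(p1.continuous @ p2.continuous) + cat_sum
    m1, m2 = p1.squared_magnitude, p2.squared_magnitude
    if m1 == 0.0 or m2 == 0.0:
        raise ValueError(
            "PSM undefined: a patient vector has zero magnitude "
            "(all-zero continuous part and no categorical dimensions)"
        )
    # for equal magnitudes num/m1 is exact at the +/-1 boundaries
    value = num / m1 if m1 == m2 else num / np.sqrt(m1 * m2)
    # absorb floating-point drift just past the cosine bounds
    return float(min(1.0, max(-1.0, value)))


@dataclass(frozen=True)
class SimilarityRanking:
    """Candidates ordered by descending PSM to one index patient.

    Ties are broken by ascending candidate id; the index patient never
    appears among the entries.
    """

    index_id: object
    entries: tuple  # of (candidate_id, psm_value)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def top_ids(self, n: int) -> list:
        if n > len(self.entries):
            raise ValueError(f"requested top {n} of a ranking of length {len(self)}")
        return [cid for cid, _ in self.entries[:n]]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("index_id\tcandidate_id\trank\tpsm\n")
            for rank, (cid, value) in enumerate(self.entries, start=1):
                fh.write(f"{self.index_id}\t{cid}\t{rank}\t{value!r}\n")


def rank_neighbors(index: PatientVector, candidates: Iterable[PatientVector]) -> SimilarityRanking:
    """Rank every candidate by PSM to the index patient (descending;
    ties by ascending candidate id)."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("cannot rank an empty candidate collection")
    if any(c.id == index.id for c in candidates):
        raise ValueError("index patient must not appear among the candidates")
    scored = [(c.id, psm(index, c)) for c in candidates]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return SimilarityRanking(index.id, tuple(scored))


# ---------------------------------------------------------------------------
# Vectorized form used by the experiment loop: the same PSM over encoded
# matrices, computed for all (test, train) pairs at once.
# ---------------------------------------------------------------------------

def encode_categoricals(*frames) -> list[np.ndarray]:
    """Integer-code categorical frames against a shared level universe.

    Codes agree across all frames, so equality of codes is equality of the
    original level strings.  Returns one (n, n_cat) int array per frame.
    """
    import pandas as pd

    if not frames:
        return []
    cols = list(frames[0].columns)
    outs = [np.empty((len(f), len(cols)), dtype=np.int64) for f in frames]
    for j, col in enumerate(cols):
        combined = pd.concat([f[col] for f in frames])
        codes = pd.factorize(combined, sort=True)[0]
        start = 0
        for i, f in enumerate(frames):
            outs[i][:, j] = codes[start : start + len(f)]
            start += len(f)
    return outs


def similarity_matrix(
    cont_a: np.ndarray,
    cat_a: np.ndarray,
    cont_b: np.ndarray,
    cat_b: np.ndarray,
) -> np.ndarray:
    """PSM between every row of A and every row of B: (n_a, n_b) array.

    ``cont_*`` are normalized continuous parts; ``cat_*`` integer-coded
    categorical parts sharing a code universe (see :func:`encode_categoricals`).
    """
    n_cat = cat_a.shape[1] if cat_a.ndim == 2 else 0
    num = cont_a @ cont_b.T
    for j in range(n_cat):
        num += np.where(cat_a[:, j, None] == cat_b[None, :, j], 1.0, -1.0)
    sq_a = (cont_a**2).sum(axis=1) + n_cat
    sq_b = (cont_b**2).sum(axis=1) + n_cat
    if np.any(sq_a == 0) or np.any(sq_b == 0):
        raise ValueError("PSM undefined for a zero-magnitude patient vector")
    sim = num / np.sqrt(np.outer(sq_a, sq_b))
    np.clip(sim, -1.0, 1.0, out=sim)
    return sim
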