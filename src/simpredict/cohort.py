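"""Patient-cohort tables and their schemas.

A cohort is a complete-case table of ICU admissions ("patients"): one row per
admission, a set of declared predictor columns (continuous or categorical), a
binary 30-day mortality outcome, and optionally one or more severity-of-illness
score columns (e.g. SAPS, SOFA) consumed as numeric benchmarks.  Each ICU
admission is treated as an independent patient; no de-duplication is attempted.

The on-disk format is a UTF-8 comma-delimited CSV plus a JSON schema sidecar
with keys ``id_column``, ``outcome_column``, ``score_columns`` and ``features``
(array of ``{"name": ..., "kind": "continuous"|"categorical"}``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("simpredict")

#: Cell contents treated as missing (case-insensitive, after stripping).
MISSING_SENTINELS = frozenset({"", "na", "nan"})

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class SchemaError(ValueError):
    """The schema is malformed or inconsistent with the table."""


class ValidationError(ValueError):
    """The table violates a cohort invariant (bad outcome, empty cohort, ...)."""


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise SchemaError(
                f"feature {self.name!r}: kind must be 'continuous' or "
                f"'categorical', got {self.kind!r}"
            )


@dataclass(frozen=True)
class CohortSchema:
    """Declares the columns of a cohort table and their roles."""

    features: tuple[Feature, ...]
    outcome_column: str
    score_columns: tuple[str, ...] = ()
    id_column: str = "patient_id"

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "score_columns", tuple(self.score_columns))
        if not self.features:
            raise SchemaError("schema must declare at least one feature")
        names = self.columns()
        dupes = {c for c in names if names.count(c) > 1}
        if dupes:
            raise SchemaError(f"duplicate column names in schema: {sorted(dupes)}")
        feat_names = {f.name for f in self.features}
        if self.outcome_column in feat_names or self.outcome_column in self.score_columns:
            raise SchemaError(
                f"outcome column {self.outcome_column!r} may not also be a "
                "feature or score column"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def continuous_features(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if f.kind == CONTINUOUS)

    @property
    def categorical_features(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if f.kind == CATEGORICAL)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def columns(self) -> list[str]:
        """All declared column names, id first, outcome last."""
        return (
            [self.id_column]
            + list(self.feature_names)
            + list(self.score_columns)
            + [self.outcome_column]
        )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id_column": self.id_column,
            "outcome_column": self.outcome_column,
            "score_columns": list(self.score_columns),
            "features": [{"name": f.name, "kind": f.kind} for f in self.features],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSchema":
        try:
            features = tuple(Feature(f["name"], f["kind"]) for f in d["features"])
            return cls(
                features=features,
                outcome_column=d["outcome_column"],
                score_columns=tuple(d.get("score_columns", ())),
                id_column=d.get("id_column", "patient_id"),
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed schema document: {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSchema":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"schema file {path} is not valid JSON: {exc}") from exc
        return cls.from_dict(doc)


@dataclass
class Cohort:
    """A validated complete-case cohort.

    ``table`` is indexed by patient id (string), sorted ascending, with
    continuous features and scores as float64, the outcome as int (0/1) and
    categorical features as plain strings.
    """

    schema: CohortSchema
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        s = self.schema
        missing = [c for c in s.columns() if c != s.id_column and c not in self.table.columns]
        if missing:
            raise SchemaError(f"table is missing schema column(s): {missing}")
        if len(self.table) == 0:
            raise ValidationError("cohort is empty")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate patient ids: {dupes[:5]}")
        out = self.table[s.outcome_column]
        bad = out[~out.isin([0, 1])]
        if len(bad):
            raise ValidationError(
                f"non-binary outcome value {bad.iloc[0]!r} for patient id "
                f"{bad.index[0]!r}"
            )
        declared = [c for c in s.columns() if c != s.id_column]
        if self.table[declared].isna().any().any():
            raise ValidationError("cohort contains missing values in declared columns")

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def outcomes(self) -> np.ndarray:
        return self.table[self.schema.outcome_column].to_numpy(dtype=int)

    @property
    def prevalence(self) -> float:
        return float(self.outcomes.mean())

    def scores(self, column: str) -> np.ndarray:
        if column not in self.schema.score_columns:
            raise SchemaError(f"{column!r} is not a declared score column")
        return self.table[column].to_numpy(dtype=float)

    def continuous_matrix(self) -> np.ndarray:
        """(n_patients, n_continuous) array in schema feature order."""
        cols = list(self.schema.continuous_features)
        if not cols:
            return np.empty((self.n, 0))
        return self.table[cols].to_numpy(dtype=float)

    def categorical_frame(self) -> pd.DataFrame:
        return self.table[list(self.schema.categorical_features)]

    def subset(self, ids: Sequence) -> "Cohort":
        """Sub-cohort restricted to ``ids`` (kept in sorted-id order)."""
        sub = self.table.loc[list(ids)].sort_index()
        return Cohort(self.schema, sub)

    def iloc_subset(self, positions: np.ndarray) -> "Cohort":
        sub = self.table.iloc[np.asarray(positions)].sort_index()
        return Cohort(self.schema, sub)

    def equals(self, other: "Cohort") -> bool:
        return self.schema == other.schema and self.table.equals(other.table)


def _coerce_types(df: pd.DataFrame, schema: CohortSchema) -> pd.DataFrame:
    numeric = list(schema.continuous_features) + list(schema.score_columns)
    for col in numeric:
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise ValidationError(f"column {col!r} has a non-numeric value: {exc}") from exc
    out = schema.outcome_column
    try:
        as_float = df[out].astype(float)
    except ValueError as exc:
        raise ValidationError(f"outcome column has a non-numeric value: {exc}") from exc
    bad = as_float[~as_float.isin([0.0, 1.0])]
    if len(bad):
        raise ValidationError(
            f"non-binary outcome value {bad.iloc[0]!r} for patient id {bad.index[0]!r}"
        )
    df[out] = as_float.astype(int)
    return df


def load_cohort(table_path: str | Path, schema_path: str | Path) -> Cohort:
    """Read a cohort CSV + JSON schema, applying complete-case filtering.

    Rows with any missing value (empty cell, ``NA`` or ``NaN``, case
    insensitive) in a declared column are dropped with a logged warning.
    Rows are sorted by patient id after load so downstream tie-breaking is
    deterministic.
    """
    schema = CohortSchema.from_json(schema_path)
    df = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in schema.columns() if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"table {table_path} is missing column(s): {missing_cols}")

    declared = schema.columns()
    cells = df[declared].apply(lambda s: s.str.strip().str.lower())
    is_missing = cells.isin(MISSING_SENTINELS)
    drop_mask = is_missing.any(axis=1)
    if drop_mask.any():
        log.warning(
            "complete-case filter dropped %d of %d rows with missing values",
            int(drop_mask.sum()),
            len(df),
        )
        df = df.loc[~drop_mask]
    if len(df) == 0:
        raise ValidationError(
            "no complete-case rows remain after filtering; cohort is empty"
        )

    df = df.set_index(schema.id_column)
    df.index.name = schema.id_column
    df = df[[c for c in declared if c != schema.id_column]]
    df = _coerce_types(df.copy(), schema)
    df = df.sort_index()
    return Cohort(schema, df)


def write_cohort(cohort: Cohort, table_path: str | Path, schema_path: str | Path) -> None:
    """Write a cohort as CSV + JSON schema so that load∘write is the identity."""
    cohort.schema.to_json(schema_path)
    out = cohort.table.reset_index()
    out = out[cohort.schema.columns()]
    out.to_csv(table_path, index=False)
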