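import numpy as np
import pandas as pd
import pytest

from simpredict import (
    CATEGORICAL,
    CONTINUOUS,
    Cohort,
    CohortSchema,
    Feature,
    GeneratorConfig,
    generate_cohort,
)


@pytest.fixture
def toy_schema() -> CohortSchema:
    return CohortSchema(
        features=(
            Feature("age", CONTINUOUS),
            Feature("hr_max", CONTINUOUS),
            Feature("service", CATEGORICAL),
        ),
        outcome_column="died",
        score_columns=("saps",),
        id_column="pid",
    )


@pytest.fixture
def toy_cohort(toy_schema) -> Cohort:
    table = pd.DataFrame(
        {
            "age": [34.0, 51.5, 70.0, 62.0, 45.0],
            "hr_max": [88.0, 110.0, 95.0, 120.0, 79.0],
            "service": ["MICU", "CCU", "MICU", "SICU", "CCU"],
            "saps": [10.0, 18.0, 14.0, 21.0, 9.0],
            "died": [0, 1, 0, 1, 0],
        },
        index=pd.Index(["p1", "p2", "p3", "p4", "p5"], name="pid"),
    )
    return Cohort(toy_schema, table)


def write_toy_csv(path, rows, header="pid,age,hr_max,service,saps,died"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


@pytest.fixture(scope="session")
def small_generated():
    """A 400-patient clustered synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=400, seed=11))


def simple_cohort(X: np.ndarray, y: np.ndarray, prefix: str = "x") -> Cohort:
    """Continuous-only cohort from a feature matrix and binary outcomes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = [f"{prefix}{j}" for j in range(X.shape[1])]
    table = pd.DataFrame(X, columns=names)
    table["outcome"] = np.asarray(y, dtype=int)
    table.index = pd.Index([f"p{i:05d}" for i in range(len(table))], name="patient_id")
    schema = CohortSchema(
        features=tuple(Feature(n, CONTINUOUS) for n in names),
        outcome_column="outcome",
        id_column="patient_id",
    )
    return Cohort(schema, table)
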