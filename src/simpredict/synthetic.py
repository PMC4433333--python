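"""Synthetic ICU-like cohort generator with latent patient subgroups.

The generator emulates the statistical structure that personalized
(similar-patient) prediction exploits: a cohort composed of latent clusters of
patients (think service lines / case-mix groups) whose features are clustered
and whose outcome mechanisms differ *by cluster*.  Concretely:

1. cluster labels follow a mildly imbalanced categorical distribution;
2. continuous features are per-cluster multivariate normal with cluster means
   separated in proportion to ``cluster_effect``, then mapped to plausible
   clinical units and clipped; correlated min/max pairs mimic the worst-value
   extraction of vitals and labs;
3. categorical features follow per-cluster multinomials (a long-tailed,
   Zipf-like distribution stands in for primary ICD-9 codes);
4. the true 30-day mortality risk is logistic in the standardized features
   with *cluster-specific* coefficient vectors — orthogonal across clusters
   under ``cluster_effect="high"``, identical under ``"none"`` — so a local
   model class can genuinely beat a global one when (and only when) cluster
   structure exists;
5. a global intercept shift is found by bisection so the mean true risk hits
   the target prevalence (default 15.1%);
6. outcomes are independent Bernoulli draws from the true risk;
7. synthetic severity scores (SAPS-like, SOFA-like) are noisy monotone
   transforms of the true risk, with the noise variance calibrated by
   bisection so each score's in-sample AUROC hits its target.

Ground truth (cluster labels, true risks, generating coefficients) is returned
alongside the cohort for recovery tests and is never consumed by the analysis
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import CATEGORICAL, CONTINUOUS, Cohort, CohortSchema, Feature
from .evaluation import auroc
from .similarity import encode_categoricals, fit_scaler, similarity_matrix

EFFECTS = ("none", "moderate", "high")

#: cluster_effect -> (latent mean-separation norm, coefficient mixing fraction,
#: categorical concentration, per-cluster intercept jitter sd)
_EFFECT_PARAMS = {
    "none": (0.0, 0.0, 0.0, 0.0),
    "moderate": (3.5, 0.5, 0.35, 0.25),
    "high": (7.0, 1.0, 0.6, 0.5),
}

_DEFAULT_CATEGORICALS = (
    ("admission_type", 3),
    ("gender", 2),
    ("service", 4),
    ("icd9", 40),
    ("vasopressor", 2),
    ("vent", 2),
)

_DEFAULT_SCORE_TARGETS = (("saps", 0.66), ("sofa", 0.63))

#: display scale (mean, sd) of the synthetic severity scores
_SCORE_SCALES = {"saps": (14.5, 5.1), "sofa": (6.3, 3.9)}

_VITALS = ("hr", "map", "sbp", "spo2", "resp", "temp")
_LABS = ("hct", "wbc", "glucose", "hco3", "potassium", "sodium", "bun", "creatinine")

#: plausible clinical units: feature family -> (loc, scale, low, high)
_UNIT_MAP = {
    "hr": (80, 15, 20, 220), "map": (75, 12, 20, 180), "sbp": (120, 20, 40, 260),
    "spo2": (95, 3, 50, 100), "resp": (18, 5, 4, 60), "temp": (37, 0.8, 32, 42),
    "hct": (33, 5, 10, 60), "wbc": (10, 5, 0.1, 60), "glucose": (130, 45, 20, 800),
    "hco3": (24, 4, 5, 45), "potassium": (4.1, 0.6, 1.5, 9), "sodium": (139, 5, 110, 170),
    "bun": (25, 18, 1, 200), "creatinine": (1.3, 1.0, 0.2, 15),
    "age": (64.5, 17, 18, 95), "gcs_min": (11, 4, 3, 15), "urine": (500, 300, 0, 4000),
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int
    seed: int = 0
    n_clusters: int = 6
    prevalence_target: float = 0.151
    cluster_effect: str = "high"
    n_continuous: int = 70
    categorical_spec: tuple = _DEFAULT_CATEGORICALS
    score_auroc_targets: tuple = _DEFAULT_SCORE_TARGETS

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence_target must be in (0, 1)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_effect not in EFFECTS:
            raise ValueError(f"cluster_effect must be one of {EFFECTS}")
        if any(n_levels < 2 for _, n_levels in self.categorical_spec):
            raise ValueError("every categorical feature needs >= 2 levels")
        for name, target in self.score_auroc_targets:
            if not (0.5 < target <= 0.999):
                raise ValueError(
                    f"score {name!r}: AUROC target {target} outside (0.5, 0.999]"
                )


@dataclass
class GeneratedCohort:
    cohort: Cohort
    truth: pd.DataFrame = field(repr=False)  # per-patient cluster + true_risk
    coefficients: dict = field(repr=False)  # cluster -> standardized-feature betas
    config: GeneratorConfig | None = None


# ---------------------------------------------------------------------------
# feature plan
# ---------------------------------------------------------------------------

def _continuous_plan(n_continuous: int):
    """Feature names, (min_idx, max_idx) pairs and unit maps.

    The default 70-feature layout mirrors first-ICU-day worst-value
    extraction: min/max of 6 vitals in four 6-hour windows (48), min/max of 8
    labs (16), age, minimum GCS, and four 6-hour urine outputs.
    """
    if n_continuous == 70:
        names, pairs, units = [], [], []
        for v in _VITALS:
            for w in range(1, 5):
                i = len(names)
                names += [f"{v}_min_w{w}", f"{v}_max_w{w}"]
                pairs.append((i, i + 1))
                units += [_UNIT_MAP[v], _UNIT_MAP[v]]
        for lab in _LABS:
            i = len(names)
            names += [f"{lab}_min", f"{lab}_max"]
            pairs.append((i, i + 1))
            units += [_UNIT_MAP[lab], _UNIT_MAP[lab]]
        names += ["age", "gcs_min"]
        units += [_UNIT_MAP["age"], _UNIT_MAP["gcs_min"]]
        names += [f"urine_out_w{w}" for w in range(1, 5)]
        units += [_UNIT_MAP["urine"]] * 4
        return names, pairs, units
    names = [f"cont_{i:03d}" for i in range(n_continuous)]
    pairs = [(i, i + 1) for i in range(0, n_continuous - 1, 2)]
    units = [(0.0, 1.0, -4.0, 4.0)] * n_continuous
    return names, pairs, units


def _default_levels(name: str, n_levels: int) -> list[str]:
    presets = {
        "admission_type": ["elective", "urgent", "emergency"],
        "gender": ["F", "M"],
        "service": ["MICU", "SICU", "CCU", "CSRU"],
        "vasopressor": ["no", "yes"],
        "vent": ["no", "yes"],
    }
    if name in presets and len(presets[name]) == n_levels:
        return presets[name]
    if name == "icd9":
        return [f"icd9_{i:03d}" for i in range(n_levels)]
    return [f"{name}_lv{i}" for i in range(n_levels)]


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------

def _bisect_intercept(lp: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Shift delta so that mean(expit(lp + delta)) = target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        value = float(expit(lp + mid).mean())
        if abs(value - target) <= tol:
            return mid
        if value < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _calibrate_score_noise(
    signal: np.ndarray, noise: np.ndarray, outcomes: np.ndarray, target: float
) -> np.ndarray:
    """Scale the fixed noise draw so auroc(signal + tau*noise) hits target."""
    ceiling = auroc(signal, outcomes)
    if target > ceiling:
        raise ValueError(
            f"score AUROC target {target:.3f} unattainable: the true risk "
            f"itself only discriminates at {ceiling:.3f} on this sample"
        )
    lo, hi = 0.0, 1.0
    while auroc(signal + hi * noise, outcomes) > target and hi < 1e4:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        value = auroc(signal + mid * noise, outcomes)
        if abs(value - target) <= 0.005:
            return signal + mid * noise
        if value > target:
            lo = mid
        else:
            hi = mid
    return signal + 0.5 * (lo + hi) * noise


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> GeneratedCohort:
    """Generate a MIMIC-like synthetic cohort with known ground truth."""
    rng = np.random.default_rng(config.seed)
    n, d, kc = config.n_patients, config.n_continuous, config.n_clusters
    separation, mix, concentration, icpt_sd = _EFFECT_PARAMS[config.cluster_effect]

    # 1. cluster labels with mild size imbalance
    weights = np.linspace(0.8, 1.2, kc)
    weights /= weights.sum()
    labels = rng.choice(kc, size=n, p=weights)

    # 2. continuous features: cluster-separated latent Gaussians
    if kc > 1 and d >= kc:
        raw_dirs = rng.standard_normal((d, kc))
        q, _ = np.linalg.qr(raw_dirs)
        means = (q[:, :kc] * separation).T  # orthogonal mean vectors, norm = separation
    else:
        means = rng.standard_normal((kc, d)) * (separation / max(np.sqrt(d), 1.0))
    Z = means[labels] + rng.standard_normal((n, d))
    names, pairs, units = _continuous_plan(d)
    for i_min, i_max in pairs:
        Z[:, i_max] = Z[:, i_min] + np.abs(rng.normal(0.0, 0.6, size=n)) + 0.05
    X = np.empty_like(Z)
    for j, (loc, scale, low, high) in enumerate(units):
        X[:, j] = np.clip(loc + scale * Z[:, j], low, high)

    # 3. categorical features: per-cluster multinomials
    cat_names = [name for name, _ in config.categorical_spec]
    cat_values = {}
    for f_idx, (name, n_levels) in enumerate(config.categorical_spec):
        levels = _default_levels(name, n_levels)
        if name == "icd9":
            base = 1.0 / np.arange(1, n_levels + 1) ** 1.1  # long-tailed
        else:
            base = np.linspace(1.0, 1.6, n_levels)
        base = base / base.sum()
        column = np.empty(n, dtype=object)
        for c in range(kc):
            mask = labels == c
            preferred = (c + f_idx) % n_levels
            probs = (1.0 - concentration) * base
            probs[preferred] += concentration
            probs /= probs.sum()
            column[mask] = rng.choice(levels, size=int(mask.sum()), p=probs)
        cat_values[name] = column

    # 4. true risk: cluster-specific logistic mechanisms on standardized features
    X_std = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    shared = rng.standard_normal(d)
    shared /= np.linalg.norm(shared)
    betas = {}
    beta_norm = 1.8
    block_assignment = np.arange(d) % kc
    for c in range(kc):
        block = rng.standard_normal(d)
        block[block_assignment != c] = 0.0
        norm = np.linalg.norm(block)
        block = block / norm if norm > 0 else block
        direction = np.sqrt(1.0 - mix) * shared + np.sqrt(mix) * block
        direction /= np.linalg.norm(direction)
        betas[c] = beta_norm * direction
    alpha = rng.normal(0.0, icpt_sd, size=kc) if icpt_sd > 0 else np.zeros(kc)
    lp = alpha[labels] + np.einsum("ij,ij->i", X_std, np.stack([betas[c] for c in labels]))

    # 5. intercept shift so mean true risk hits the prevalence target
    shift = _bisect_intercept(lp, config.prevalence_target)
    true_risk = expit(lp + shift)

    # 6. outcomes
    outcomes = rng.binomial(1, true_risk)

    # 7. severity scores: noisy monotone transforms of the true risk
    score_cols = {}
    signal = logit(true_risk)
    for name, target in config.score_auroc_targets:
        noise = rng.standard_normal(n)
        raw = _calibrate_score_noise(signal, noise, outcomes, target)
        loc, scale = _SCORE_SCALES.get(name, (0.0, 1.0))
        score_cols[name] = loc + scale * (raw - raw.mean()) / raw.std()

    # assemble cohort
    ids = [f"p{i:06d}" for i in range(n)]
    table = pd.DataFrame(X, columns=names, index=pd.Index(ids, name="patient_id"))
    for name in cat_names:
        table[name] = cat_values[name]
    for name, values in score_cols.items():
        table[name] = values
    table["mortality_30d"] = outcomes.astype(int)

    schema = CohortSchema(
        features=tuple(
            [Feature(name, CONTINUOUS) for name in names]
            + [Feature(name, CATEGORICAL) for name in cat_names]
        ),
        outcome_column="mortality_30d",
        score_columns=tuple(score_cols),
        id_column="patient_id",
    )
    cohort = Cohort(schema, table)
    truth = pd.DataFrame(
        {"cluster": labels, "true_risk": true_risk},
        index=pd.Index(ids, name="patient_id"),
    )
    return GeneratedCohort(cohort=cohort, truth=truth, coefficients=betas, config=config)


def cluster_recovery_check(
    generated: GeneratedCohort,
    n_sample: int = 200,
    top: int = 25,
    seed: int = 0,
) -> float:
    """Fraction of top-``top`` PSM neighbors sharing the index patient's
    latent cluster, averaged over a sample of index patients.

    With a single cluster the answer is trivially 1.0.
    """
    clusters = generated.truth["cluster"].to_numpy()
    if len(np.unique(clusters)) == 1:
        return 1.0
    cohort = generated.cohort
    scaler = fit_scaler(cohort)
    cont = scaler.transform(cohort.continuous_matrix())
    (cat,) = encode_categoricals(cohort.categorical_frame())
    rng = np.random.default_rng(seed)
    sample = rng.choice(cohort.n, size=min(n_sample, cohort.n), replace=False)
    sim = similarity_matrix(cont[sample], cat[sample], cont, cat)
    sim[np.arange(len(sample)), sample] = -np.inf  # exclude self
    agreement = []
    for row, idx in zip(sim, sample):
        neighbors = np.argpartition(-row, top)[:top]
        agreement.append(float(np.mean(clusters[neighbors] == clusters[idx])))
    return float(np.mean(agreement))
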