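"""Synthetic standardization-cohort generator.

Real standardization samples of commercial intelligence batteries are
proprietary, so every downstream stage of this package is exercised on
cohorts simulated from a one-general-factor model:

    x_j = lambda_j(g) * g + sqrt(psi_j) * s_j + sqrt(theta_j) * e_j

with g, s_j, e_j independent standard normals, specific variance
psi_j = r_j - lambda_j(g)^2 and error variance theta_j = 1 - r_j fixed by
the subtest's target reliability r_j.  An optional SLODR term (Spearman's
law of diminishing returns) attenuates loadings linearly above the mean:
lambda_j(g) = lambda_j * (1 - delta * max(0, g)), floored at 0.  Scores are
mapped to the scaled-score metric (mean 10, SD 3), optionally rounded to
integers and floored/ceilinged.  School grades on the Swiss 1-6 ladder are
generated with a configurable validity (correlation with latent g).

Latent quantities (g and the error-free subtest scores) are retained in the
cohort table under reserved column names so that parameter-recovery and
coverage tests can see the generating truth; they are never treated as
observable by the analysis stages and are dropped on export by default.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .battery import BatteryConfig, round_half_up

#: Latent (non-observable) column names start with these prefixes.
LATENT_PREFIXES = ("g", "true_")


def latent_columns(cohort: pd.DataFrame) -> list[str]:
    """Columns of a cohort table that hold generating (non-observable) values."""
    return [c for c in cohort.columns if c == "g" or c.startswith("true_")]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named random substream: one root seed, independent stream per stage.

    Adding a stage never perturbs another stage's draws because each stream
    is keyed by (root seed, crc32 of the stage name).
    """
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(stage.encode()))))


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated standardization cohort.

    Loadings and reliabilities come from the embedded battery; the remaining
    fields set sample size, SLODR slope, score discretization/truncation,
    grade validity and covariate prevalences.  ``language_prevalences`` are
    (monolingual-German, bilingual, other-language) probabilities.
    """

    battery: BatteryConfig
    n_subjects: int = 1600
    seed: int = 0
    slodr_slope: float = 0.0
    discretize: bool = True
    score_floor: int | None = None
    score_ceiling: int | None = None
    grade_validity: float = 0.5
    grade_fraction: float = 0.25
    grade_subjects: tuple[str, ...] = (
        "german", "math", "social_studies", "history_geography", "science"
    )
    sex_prevalence: float = 0.5
    adhd_prevalence: float = 0.05
    language_prevalences: tuple[float, float, float] = (0.80, 0.12, 0.08)
    education_prevalence: float = 0.30
    participation_mean: float = 10.0
    participation_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.slodr_slope < 0:
            raise ValueError("slodr_slope must be >= 0")
        if not 0.0 <= self.grade_validity < 1.0:
            raise ValueError("grade_validity must be in [0, 1)")
        for p in (self.sex_prevalence, self.adhd_prevalence, self.education_prevalence):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")
        if abs(sum(self.language_prevalences) - 1.0) > 1e-9:
            raise ValueError("language prevalences must sum to 1")


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw a cohort table from the one-general-factor model.

    Fully reproducible from ``config.seed``; ages are uniform over the
    battery's age range, covariates Bernoulli/categorical with the
    configured prevalences, and the participation rating an integer
    scaled score with the configured mean and SD.
    """
    battery = config.battery
    n = config.n_subjects
    rng = stage_rng(config.seed, "cohort")

    lo = battery.age_bands[0][0]
    hi = battery.age_bands[-1][1]
    age = rng.uniform(lo, np.nextafter(hi, lo), size=n)

    g = rng.standard_normal(n)
    data: dict[str, np.ndarray] = {
        "id": np.arange(1, n + 1),
        "age": np.round(age, 2),
        "sex": (rng.random(n) < config.sex_prevalence).astype(int),
        "adhd": (rng.random(n) < config.adhd_prevalence).astype(int),
        "language": rng.choice(
            ["monolingual", "bilingual", "other"], size=n, p=config.language_prevalences
        ),
        "education": (rng.random(n) < config.education_prevalence).astype(int),
        "participation": np.round(
            config.participation_mean + config.participation_sd * rng.standard_normal(n)
        ).astype(int),
        "g": g,
    }

    clamped = 0
    for sub in battery.subtests:
        lam = sub.loading * np.maximum(0.0, 1.0 - config.slodr_slope * np.maximum(0.0, g))
        psi = sub.reliability - lam**2
        neg = psi < 0
        if neg.any():
            clamped += int(neg.sum())
            psi = np.maximum(psi, 0.0)
        theta = 1.0 - sub.reliability
        true_part = lam * g + np.sqrt(psi) * rng.standard_normal(n)
        x = true_part + np.sqrt(theta) * rng.standard_normal(n)
        scaled = 10.0 + 3.0 * x
        if config.discretize:
            scaled = np.floor(scaled + 0.5)
        if config.score_floor is not None:
            scaled = np.maximum(scaled, config.score_floor)
        if config.score_ceiling is not None:
            scaled = np.minimum(scaled, config.score_ceiling)
        data[sub.name] = scaled
        data[f"true_{sub.name}"] = 10.0 + 3.0 * true_part

    if clamped:
        warnings.warn(
            f"SLODR adjustment drove specific variance below 0 for {clamped} "
            "subject-subtest draws; clamped to 0",
            stacklevel=2,
        )

    cols = (
        ["id", "age", "sex", "adhd", "language", "education", "participation", "g"]
        + [s.name for s in battery.subtests]
        + [f"true_{s.name}" for s in battery.subtests]
    )
    return pd.DataFrame(data)[cols]


def _round_to_half(x: np.ndarray) -> np.ndarray:
    return np.floor(2.0 * x + 0.5) / 2.0


def generate_grades(
    cohort: pd.DataFrame,
    validity: float,
    seed: int,
    subjects: tuple[str, ...] = ("german", "math"),
    fraction: float = 1.0,
) -> pd.DataFrame:
    """Attach school grades correlated with latent ability.

    Each grade is clip(round-to-half(4.5 + 0.8 * (gamma*g + sqrt(1-gamma^2)*eps)), 1, 6)
    on the Swiss 1-6 ladder in 0.5 steps, with an independent eps per school
    subject.  Only a random ``fraction`` of subjects receives grades
    (emulating the parent-report subsample); the rest get missing values.
    """
    if "g" not in cohort.columns:
        raise ValueError("cohort lacks the latent 'g' column needed to generate grades")
    if not 0.0 <= validity < 1.0:
        raise ValueError("validity must be in [0, 1)")
    rng = stage_rng(seed, "grades")
    out = cohort.copy()
    n = len(cohort)
    has_grades = rng.random(n) < fraction
    g = cohort["g"].to_numpy(float)
    for subject in subjects:
        eps = rng.standard_normal(n)
        raw = 4.5 + 0.8 * (validity * g + np.sqrt(1.0 - validity**2) * eps)
        grade = np.clip(_round_to_half(raw), 1.0, 6.0)
        grade[~has_grades] = np.nan
        out[f"grade_{subject}"] = grade
    return out


def generate_study_cohort(config: SimConfig) -> pd.DataFrame:
    """Cohort plus grades in one call, all randomness from ``config.seed``."""
    cohort = generate_cohort(config)
    return generate_grades(
        cohort,
        validity=config.grade_validity,
        seed=config.seed,
        subjects=config.grade_subjects,
        fraction=config.grade_fraction,
    )


def population_covariance(config: SimConfig) -> pd.DataFrame:
    """Population covariance of the subtest scores on the standard scale.

    Valid for slodr_slope = 0 and continuous (non-discretized, untruncated)
    scores: cov(x_i, x_j) = lambda_i * lambda_j for i != j and var(x_j) = 1.
    Used as the analytic oracle for structural tests.
    """
    lams = np.array([s.loading for s in config.battery.subtests])
    cov = np.outer(lams, lams)
    np.fill_diagonal(cov, 1.0)
    names = [s.name for s in config.battery.subtests]
    return pd.DataFrame(cov, index=names, columns=names)


def population_composite_correlation(config: SimConfig, comp_a: str, comp_b: str) -> float:
    """Population correlation of two unit-weighted composite sums (delta = 0)."""
    cov = population_covariance(config)
    a = list(config.battery.composite(comp_a).members)
    b = list(config.battery.composite(comp_b).members)
    cov_ab = float(cov.loc[a, b].to_numpy().sum())
    var_a = float(cov.loc[a, a].to_numpy().sum())
    var_b = float(cov.loc[b, b].to_numpy().sum())
    return cov_ab / np.sqrt(var_a * var_b)


def population_composite_reliability(config: SimConfig, composite: str) -> float:
    """Population reliability of a composite sum from the generating model.

    True-score variance of x_j is r_j (common lambda_j^2 plus specific
    psi_j); errors are independent across subtests, so the composite's
    error variance is the sum of the theta_j.
    """
    comp = config.battery.composite(composite)
    cov = population_covariance(config)
    members = list(comp.members)
    var_total = float(cov.loc[members, members].to_numpy().sum())
    err = sum(1.0 - config.battery.subtest(m).reliability for m in members)
    return 1.0 - err / var_total
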