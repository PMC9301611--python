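"""Configuration files, cohort readers/writers, and the end-to-end pipeline.

Battery and simulation configurations are YAML; cohorts, norm tables,
reliability lookups and all result tables are comma-separated UTF-8 text with
a period decimal mark and the empty string for missing values.  All
randomness flows from one root seed through named substreams, so adding a
pipeline stage never perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .battery import (
    BatteryConfig,
    CompositeSpec,
    NormTable,
    SubtestSpec,
    build_norm_table,
    compute_composite_iqs,
)
from .comparability import (
    CRITERIA,
    abs_difference_summary,
    compare_pair,
    comparability_rates,
    group_level_comparison,
)
from .regression import (
    beta_ci_overlap_fraction,
    fit_gamma_glm,
    fit_grade_regression,
    likelihood_ratio_test,
    median_split,
    two_sd_standardize,
)
from .reliability import build_reliability_lookup
from .simulate import SimConfig, generate_study_cohort, latent_columns

log = logging.getLogger("gicomp")


# --- battery / simulation configuration ----------------------------------

def battery_to_dict(battery: BatteryConfig) -> dict:
    return {
        "name": battery.name,
        "age_bands": [list(b) for b in battery.age_bands],
        "subtests": [
            {k: v for k, v in {
                "name": s.name, "ability": s.ability, "loading": s.loading,
                "reliability": s.reliability, "retest": s.retest,
            }.items() if v is not None}
            for s in battery.subtests
        ],
        "composites": [
            {k: v for k, v in {
                "name": c.name, "members": list(c.members),
                "clip_range": list(c.clip_range), "retest": c.retest,
            }.items() if v is not None}
            for c in battery.composites
        ],
    }


def battery_from_dict(data: dict) -> BatteryConfig:
    return BatteryConfig(
        name=data["name"],
        subtests=tuple(SubtestSpec(**s) for s in data["subtests"]),
        composites=tuple(
            CompositeSpec(
                name=c["name"],
                members=tuple(c["members"]),
                clip_range=tuple(c.get("clip_range", (55, 145))),
                retest=c.get("retest"),
            )
            for c in data["composites"]
        ),
        age_bands=tuple(tuple(b) for b in data["age_bands"]),
    )


def read_battery_config(path) -> BatteryConfig:
    with open(path) as fh:
        return battery_from_dict(yaml.safe_load(fh))


def write_battery_config(battery: BatteryConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(battery_to_dict(battery), fh, sort_keys=False)


def sim_config_from_dict(data: dict, battery: BatteryConfig) -> SimConfig:
    kwargs = dict(data)
    for key in ("language_prevalences", "grade_subjects"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimConfig(battery=battery, **kwargs)


def read_sim_config(path, battery: BatteryConfig) -> SimConfig:
    with open(path) as fh:
        return sim_config_from_dict(yaml.safe_load(fh) or {}, battery)


# --- cohort I/O -----------------------------------------------------------

_COVARIATE_COLUMNS = ("id", "age", "sex", "adhd", "language", "education", "participation")


def read_cohort(path, battery: BatteryConfig) -> pd.DataFrame:
    """Read a cohort table, validating it against the battery schema.

    Required: ``age`` and one column per battery subtest.  Recognized
    extras: the standard covariates, ``grade_*`` columns (validated to the
    1-6 scale) and latent ``g`` / ``true_*`` columns.  Anything else, or an
    out-of-range grade, raises with row/column coordinates.
    """
    df = pd.read_csv(path)
    known = set(_COVARIATE_COLUMNS) | set(battery.subtest_names) | {"g"}
    missing = [s for s in ("age", *battery.subtest_names) if s not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required columns: {missing}")
    for col in df.columns:
        if col in known or col.startswith("grade_") or col.startswith("true_"):
            continue
        raise ValueError(f"cohort file {path}: unknown column {col!r}")
    for col in df.columns:
        if col.startswith("grade_"):
            vals = df[col]
            bad = vals.notna() & ((vals < 1) | (vals > 6))
            if bad.any():
                row = int(bad.idxmax())
                raise ValueError(
                    f"cohort file {path}: grade {vals[row]} outside the 1-6 scale "
                    f"at row {row}, column {col!r}"
                )
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(1, len(df) + 1))
    log.info("read cohort of %d subjects from %s", len(df), path)
    return df


def write_cohort(cohort: pd.DataFrame, path, include_latent: bool = False) -> None:
    out = cohort if include_latent else cohort.drop(columns=latent_columns(cohort))
    out.to_csv(path, index=False)


# --- the full analysis ----------------------------------------------------

@dataclass
class RunConfig:
    """Everything one end-to-end analysis needs.

    ``cohort`` is either a path to a cohort file or a SimConfig to simulate
    one.  ``pairs`` lists (composite_a, composite_b) comparisons; criteria
    default to all six.
    """

    battery: BatteryConfig
    cohort: SimConfig | str | Path
    pairs: tuple[tuple[str, str], ...]
    criteria: tuple[str, ...] = CRITERIA
    outdir: str | Path = "results"
    seed: int = 0
    min_cell: int = 30

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("at least one composite pair is required")
        if not self.criteria:
            raise ValueError("at least one criterion is required")
        for a, b in self.pairs:
            self.battery.composite(a)
            self.battery.composite(b)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "battery": battery_to_dict(config.battery),
            "cohort": str(config.cohort),
            "pairs": [list(p) for p in config.pairs],
            "criteria": list(config.criteria),
            "seed": config.seed,
            "min_cell": config.min_cell,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _grade_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c.startswith("grade_")]


def build_difference_design(
    cohort: pd.DataFrame,
    iq_level_source: pd.Series,
) -> pd.DataFrame:
    """Predictor table for the gamma GLM of absolute IQ differences.

    Age, sex, AD(H)D, native-language dummies, education, participation and
    IQ-level dummies (below-/above-average on the referenced composite),
    plus age-by-IQ-level interactions.  Main effects are 2SD-standardized
    first; interaction columns are products of standardized mains.
    Constant columns (e.g. an unobserved covariate level) are dropped with
    a log note.
    """
    design = pd.DataFrame(index=cohort.index)
    design["age"] = cohort["age"].astype(float)
    for col in ("sex", "adhd", "education"):
        if col in cohort.columns:
            design[col] = cohort[col].astype(float)
    if "language" in cohort.columns:
        design["bilingual"] = (cohort["language"] == "bilingual").astype(float)
        design["other_language"] = (cohort["language"] == "other").astype(float)
    if "participation" in cohort.columns:
        design["participation"] = cohort["participation"].astype(float)
    design["below_average_iq"] = (iq_level_source < 85).astype(float)
    design["above_average_iq"] = (iq_level_source > 115).astype(float)

    constant = [c for c in design.columns if design[c].std(ddof=0) == 0]
    if constant:
        log.info("dropping constant predictors: %s", constant)
        design = design.drop(columns=constant)
    design = two_sd_standardize(design)
    for lvl in ("below_average_iq", "above_average_iq"):
        if lvl in design.columns:
            design[f"age_x_{lvl}"] = design["age"] * design[lvl]
    return design


def run_full_analysis(config: RunConfig) -> dict[str, pd.DataFrame | dict]:
    """Norming, IQs, differences, six criteria, validity and GLM — end to end.

    Writes every result table plus a provenance sidecar to
    ``config.outdir`` and returns them keyed by table name.  Deterministic
    given the config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    battery = config.battery

    stage = "load-cohort"
    try:
        if isinstance(config.cohort, SimConfig):
            cohort = generate_study_cohort(config.cohort)
        else:
            cohort = read_cohort(config.cohort, battery)
        n_input = len(cohort)

        stage = "norming"
        norms = build_norm_table(cohort, battery)
        norms.to_frame().to_csv(outdir / "norms.csv", index=False)

        stage = "reliability"
        lookup = build_reliability_lookup(cohort, battery, norms, min_cell=config.min_cell)
        lookup.to_frame().to_csv(outdir / "reliability.csv", index=False)

        stage = "composite-iqs"
        iqs = compute_composite_iqs(cohort, battery, norms)
        iqs.describe().to_csv(outdir / "composite_iq_descriptives.csv")

        results: dict[str, pd.DataFrame | dict] = {
            "norms": norms.to_frame(),
            "reliability": lookup.to_frame(),
        }
        grade_cols = _grade_columns(cohort)
        if grade_cols:
            gpa_col = cohort[grade_cols].mean(axis=1)

        for comp_a, comp_b in config.pairs:
            tag = f"{comp_a}_vs_{comp_b}"
            stage = f"pair {tag}"
            pair = compare_pair(cohort, battery, norms, comp_a, comp_b, lookup)
            analyzed = pair.n
            assert analyzed + (n_input - analyzed) == n_input  # no silent subject loss

            summary = abs_difference_summary(pair)
            glc = group_level_comparison(
                pair, lookup.overall[comp_a], lookup.overall[comp_b]
            )
            summary_df = pd.DataFrame(
                [
                    {"statistic": "n", "value": pair.n},
                    {"statistic": "mean_abs_diff", "value": summary["abs"]["mean"]},
                    {"statistic": "median_abs_diff", "value": summary["abs"]["median"]},
                    {"statistic": "min_abs_diff", "value": summary["abs"]["min"]},
                    {"statistic": "max_abs_diff", "value": summary["abs"]["max"]},
                    {"statistic": "t", "value": glc.t},
                    {"statistic": "df", "value": glc.df},
                    {"statistic": "p", "value": glc.p},
                    {"statistic": "cohens_d", "value": glc.d},
                    {"statistic": "r", "value": glc.r},
                    {"statistic": "r_corrected", "value": glc.r_corr},
                ]
            )
            summary_df.to_csv(outdir / f"pair_{tag}_summary.csv", index=False)
            results[f"pair_{tag}_summary"] = summary_df

            stage = f"rates {tag}"
            rate_frames = []
            for crit in config.criteria:
                for grouping in ("overall", "iq", "age"):
                    rt = comparability_rates(pair, crit, grouping)
                    rt.insert(0, "criterion", crit)
                    rt.insert(1, "grouping", grouping)
                    rate_frames.append(rt)
            rates = pd.concat(rate_frames, ignore_index=True)
            rates["n_excluded"] = rates["criterion"].map(pair.excluded)
            rates.to_csv(outdir / f"rates_{tag}.csv", index=False)
            results[f"rates_{tag}"] = rates

            if grade_cols:
                stage = f"validity {tag}"
                val_rows = []
                splits = {"all": pair.table, **dict(zip(("small", "large"),
                          (median_split(pair).small, median_split(pair).large)))}
                outcomes = {"gpa": gpa_col, "german": cohort.get("grade_german"),
                            "math": cohort.get("grade_math")}
                for split_name, subtable in splits.items():
                    idx = subtable.index
                    for out_name, out_vals in outcomes.items():
                        if out_vals is None:
                            continue
                        fits = {}
                        for comp, col in ((comp_a, "iq_a"), (comp_b, "iq_b")):
                            try:
                                fits[comp] = fit_grade_regression(
                                    out_vals.loc[idx], subtable[col],
                                    out_name, comp,
                                )
                            except ValueError:
                                fits[comp] = None
                        both = all(f is not None for f in fits.values())
                        frac, different = (
                            beta_ci_overlap_fraction(fits[comp_a].ci, fits[comp_b].ci)
                            if both else (np.nan, None)
                        )
                        for comp, fit in fits.items():
                            if fit is None:
                                continue
                            val_rows.append({
                                "subsample": split_name, "outcome": out_name,
                                "composite": comp, "beta": fit.beta,
                                "beta_ci_lower": fit.ci.lower,
                                "beta_ci_upper": fit.ci.upper,
                                "r2": fit.r2, "n": fit.n,
                                "ci_overlap_fraction": frac,
                                "betas_different": different,
                            })
                validity = pd.DataFrame(val_rows)
                validity.to_csv(outdir / f"validity_{tag}.csv", index=False)
                results[f"validity_{tag}"] = validity

            stage = f"glm {tag}"
            if pair.abs_diff.nunique() <= 1:
                log.info("skipping GLM for %s: absolute differences are constant", tag)
                continue
            base = comp_a if battery.composite(comp_a).k >= battery.composite(comp_b).k else comp_b
            design = build_difference_design(cohort, iqs[base])
            full = fit_gamma_glm(pair.abs_diff.to_numpy(float), design)
            null = fit_gamma_glm(pair.abs_diff.to_numpy(float), None)
            lrt = likelihood_ratio_test(full, null)
            glm_df = pd.DataFrame({
                "coefficient": full.params,
                "se": full.bse,
                "p": full.pvalues,
            })
            glm_df.index.name = "predictor"
            glm_df = glm_df.reset_index()
            glm_df["n"] = full.n
            glm_df["lrt_statistic"] = lrt.statistic
            glm_df["lrt_df"] = lrt.df
            glm_df["lrt_p"] = lrt.p
            glm_df.to_csv(outdir / f"glm_{tag}.csv", index=False)
            results[f"glm_{tag}"] = glm_df
    except Exception as err:
        raise RuntimeError(f"analysis aborted at stage: {stage}") from err

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_subjects": int(n_input),
        "pairs": [list(p) for p in config.pairs],
        "criteria": list(config.criteria),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    results["provenance"] = provenance
    return results
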