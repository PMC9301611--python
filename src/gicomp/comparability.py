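"""True-score confidence intervals and individual-level comparability criteria.

Two IQs from the same battery are deemed *comparable* for one subject if
their intervals overlap.  Six rules differ in what the interval is:

- ``NomIQ``      — the nominal category itself (point "interval"): categories equal;
- ``CI_overall`` — 95% true-score CI with the composite's overall internal consistency;
- ``CI_age``     — same, with the age-band-specific coefficient;
- ``CI_ageIQ``   — same, with the age-by-IQ-group-specific coefficient;
- ``CI_rtt``     — same, with the test-retest coefficient;
- ``NomCI``      — the nominal categories spanned by the overall-coefficient CIs intersect.

The true-score CI is built from the estimated true score
T = 100 + r (X - 100) and the standard error of estimate
SE_E = 15 sqrt(r (1 - r)):  T +/- z * SE_E.  Bounds stay unrounded for
overlap tests; only reported widths are rounded (half-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .battery import (
    BatteryConfig,
    NormTable,
    assign_iq_group,
    compute_composite_iqs,
    round_half_up,
)
from .intervals import Interval, intervals_overlap  # noqa: F401  (re-exported)
from .reliability import ReliabilityLookup, disattenuate

#: The six comparability criteria, in reporting order.
CRITERIA = ("NomIQ", "CI_overall", "CI_age", "NomCI", "CI_rtt", "CI_ageIQ")

IQ_SD = 15.0
IQ_MEAN = 100.0


def _z(level: float) -> float:
    # exact normal quantile (1.959964 at level .95), not the rounded 1.96
    return float(stats.norm.ppf(0.5 + level / 2.0))


@dataclass(frozen=True)
class CriterionSpec:
    """One comparability rule plus the confidence level its CIs use."""

    kind: str
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.kind not in CRITERIA:
            raise ValueError(f"unknown criterion kind {self.kind!r}; one of {CRITERIA}")
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")


def estimated_true_score(iq: float, r: float) -> float:
    """Regression-to-the-mean-adjusted score: 100 + r (X - 100)."""
    if not 0.0 < r <= 1.0:
        raise ValueError("reliability must be in (0, 1]")
    return IQ_MEAN + r * (iq - IQ_MEAN)


def true_score_ci(iq: float, r: float, level: float = 0.95) -> Interval:
    """True-score CI: estimated true score +/- z * SE_E, bounds unrounded.

    SE_E = 15 sqrt(r (1 - r)) is the SD of observed scores around the
    estimated true score.
    """
    t = estimated_true_score(iq, r)
    half = _z(level) * IQ_SD * np.sqrt(r * (1.0 - r))
    return Interval(t - half, t + half)


def ci_width_points(r: float, level: float = 0.95) -> int:
    """Reported CI width in IQ points: round-half-up of 2 z 15 sqrt(r(1-r))."""
    if not 0.0 < r <= 1.0:
        raise ValueError("reliability must be in (0, 1]")
    return round_half_up(2.0 * _z(level) * IQ_SD * np.sqrt(r * (1.0 - r)))


# --- vectorized internals -------------------------------------------------

_CAT_CUTS = np.array([70, 85, 116, 131])


def _cat_codes(iq: np.ndarray) -> np.ndarray:
    """Nominal-category index (0..4) per integer IQ, vectorized."""
    return np.searchsorted(_CAT_CUTS, iq, side="right")


def _ci_bounds(iq: np.ndarray, r: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    t = IQ_MEAN + r * (iq - IQ_MEAN)
    half = _z(level) * IQ_SD * np.sqrt(r * (1.0 - r))
    return t - half, t + half


def evaluate_criterion(
    iq_a: int,
    iq_b: int,
    criterion: CriterionSpec,
    lookup: ReliabilityLookup,
    comp_a: str,
    comp_b: str,
    band: tuple[float, float] | None = None,
) -> bool | None:
    """Comparability flag for one subject under one criterion.

    Returns None (subject excluded) when a required reliability cell is
    unavailable.  For ``CI_ageIQ`` each composite's cell is indexed by that
    composite's own observed IQ.
    """
    kind = criterion.kind
    if kind == "NomIQ":
        return bool(_cat_codes(np.array([iq_a]))[0] == _cat_codes(np.array([iq_b]))[0])
    grp_a = assign_iq_group(iq_a, "3") if kind == "CI_ageIQ" else None
    grp_b = assign_iq_group(iq_b, "3") if kind == "CI_ageIQ" else None
    r_a = lookup.get(kind, comp_a, band, grp_a)
    r_b = lookup.get(kind, comp_b, band, grp_b)
    if r_a is None or r_b is None:
        return None
    ci_a = true_score_ci(iq_a, r_a, criterion.level)
    ci_b = true_score_ci(iq_b, r_b, criterion.level)
    if kind == "NomCI":
        from .battery import interval_to_categories

        return bool(set(interval_to_categories(ci_a)) & set(interval_to_categories(ci_b)))
    return intervals_overlap(ci_a, ci_b)


@dataclass
class PairComparison:
    """One composite pair evaluated over a cohort.

    ``table`` has one row per subject with both IQs: the two IQs, the signed
    and absolute difference, the 6-level IQ group (based on the composite
    with more subtests), the age-band label, and one nullable-boolean flag
    column per evaluated criterion (pd.NA = excluded for that criterion).
    ``excluded`` counts exclusions per criterion.
    """

    comp_a: str
    comp_b: str
    table: pd.DataFrame
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def abs_diff(self) -> pd.Series:
        return self.table["abs_diff"]

    @property
    def signed_diff(self) -> pd.Series:
        return self.table["diff"]


def compare_pair(
    cohort: pd.DataFrame,
    battery: BatteryConfig,
    norms: NormTable,
    comp_a: str,
    comp_b: str,
    lookup: ReliabilityLookup | None = None,
    criteria: Sequence[CriterionSpec] | None = None,
    level: float = 0.95,
) -> PairComparison:
    """Build a PairComparison for two composites over a cohort.

    Computes both IQs (age-band normed, clipped, integer), their signed and
    absolute differences, and — when a reliability lookup is supplied — the
    flags of every requested criterion (default: all six).
    """
    if criteria is None:
        criteria = [CriterionSpec(kind, level) for kind in CRITERIA]
    iqs = compute_composite_iqs(cohort, battery, norms, [comp_a, comp_b])
    a = iqs[comp_a].to_numpy(int)
    b = iqs[comp_b].to_numpy(int)
    bands = [battery.age_band_of(x) for x in cohort["age"]]
    base = a if battery.composite(comp_a).k >= battery.composite(comp_b).k else b
    table = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy() if "id" in cohort else np.arange(1, len(cohort) + 1),
            "age": cohort["age"].to_numpy(),
            "age_band": [battery.band_label(bd) for bd in bands],
            "iq_a": a,
            "iq_b": b,
            "diff": a - b,
            "abs_diff": np.abs(a - b),
            "iq_group6": [assign_iq_group(int(q), "6") for q in base],
        }
    )

    excluded: dict[str, int] = {}
    if lookup is not None:
        band_arr = np.array(bands, dtype=object)
        for crit in criteria:
            flags = _evaluate_vectorized(a, b, band_arr, crit, lookup, comp_a, comp_b)
            table[crit.kind] = pd.array(flags, dtype="boolean")
            excluded[crit.kind] = int(pd.isna(flags).sum())
    return PairComparison(comp_a, comp_b, table, excluded)


def _reliability_vector(
    kind: str,
    lookup: ReliabilityLookup,
    composite: str,
    bands: np.ndarray,
    iqs: np.ndarray,
) -> np.ndarray:
    """Per-subject reliability for one composite under one criterion (NaN = unavailable)."""
    n = len(iqs)
    if kind in ("CI_overall", "NomCI"):
        r = lookup.overall.get(composite)
        return np.full(n, np.nan if r is None else r)
    if kind == "CI_rtt":
        r = lookup.retest.get(composite)
        return np.full(n, np.nan if r is None else r)
    out = np.full(n, np.nan)
    if kind == "CI_age":
        for band in set(map(tuple, bands)):
            r = lookup.by_age.get((composite, band))
            if r is not None:
                out[np.array([tuple(x) == band for x in bands])] = r
        return out
    if kind == "CI_ageIQ":
        groups = np.array([assign_iq_group(int(q), "3") for q in iqs], dtype=object)
        for band in set(map(tuple, bands)):
            in_band = np.array([tuple(x) == band for x in bands])
            for grp in ("below_average", "average", "above_average"):
                r = lookup.by_age_iq.get((composite, band, grp))
                if r is not None:
                    out[in_band & (groups == grp)] = r
        return out
    raise ValueError(f"unknown CI criterion kind {kind!r}")


def _evaluate_vectorized(
    a: np.ndarray,
    b: np.ndarray,
    bands: np.ndarray,
    crit: CriterionSpec,
    lookup: ReliabilityLookup,
    comp_a: str,
    comp_b: str,
) -> np.ndarray:
    """Object array of True/False/pd.NA flags, matching evaluate_criterion."""
    if crit.kind == "NomIQ":
        return (_cat_codes(a) == _cat_codes(b)).astype(object)
    r_a = _reliability_vector(crit.kind, lookup, comp_a, bands, a)
    r_b = _reliability_vector(crit.kind, lookup, comp_b, bands, b)
    ok = ~(np.isnan(r_a) | np.isnan(r_b))
    lo_a, hi_a = _ci_bounds(a.astype(float), r_a, crit.level)
    lo_b, hi_b = _ci_bounds(b.astype(float), r_b, crit.level)
    if crit.kind == "NomCI":
        # category-run overlap of the two CI category spans
        ca_lo = _cat_codes(np.floor(lo_a + 0.5))
        ca_hi = _cat_codes(np.floor(hi_a + 0.5))
        cb_lo = _cat_codes(np.floor(lo_b + 0.5))
        cb_hi = _cat_codes(np.floor(hi_b + 0.5))
        res = (ca_lo <= cb_hi) & (cb_lo <= ca_hi)
    else:
        res = (lo_a <= hi_b) & (lo_b <= hi_a)
    out = res.astype(object)
    out[~ok] = pd.NA
    return out


def comparability_rates(
    pair: PairComparison, criterion: str, grouping: str = "overall"
) -> pd.DataFrame:
    """Percent comparable subjects per cell, with cell n.

    ``grouping`` is ``overall``, ``iq`` (6-level IQ groups on the composite
    with more subtests) or ``age`` (battery age bands).  Excluded subjects
    (flag NA) do not enter numerator or denominator; empty cells report
    n = 0 and a missing rate.
    """
    if criterion not in pair.table.columns:
        raise KeyError(f"criterion {criterion!r} not evaluated for this pair")
    flags = pair.table[criterion]
    if grouping == "overall":
        keys = pd.Series("overall", index=pair.table.index)
    elif grouping == "iq":
        keys = pair.table["iq_group6"]
    elif grouping == "age":
        keys = pair.table["age_band"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for key in keys.unique():
        f = flags[keys == key].dropna()
        rows.append(
            {
                "group": key,
                "n": int(len(f)),
                "pct_comparable": 100.0 * f.mean() if len(f) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def abs_difference_summary(pair: PairComparison) -> dict[str, dict[str, float]]:
    """Sample moments of the absolute and signed IQ differences.

    mean, median, (min, max), skewness and excess kurtosis; mirrors the
    descriptive columns of a difference-summary table.
    """
    if pair.n < 1:
        raise ValueError("need at least one subject")
    out = {}
    for label, x in (("abs", pair.abs_diff), ("signed", pair.signed_diff)):
        v = x.to_numpy(float)
        out[label] = {
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "min": float(v.min()),
            "max": float(v.max()),
            "skewness": float(stats.skew(v)) if v.std() > 0 else float("nan"),
            "kurtosis": float(stats.kurtosis(v)) if v.std() > 0 else float("nan"),
        }
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Group-level agreement of two composites: paired t, Dunlap d, r, r_corr."""

    t: float
    df: int
    p: float
    d: float
    r: float
    r_corr: float
    n: int


def paired_cohens_d(t: float, r: float, n: int) -> float:
    """Paired-samples Cohen's d from t, the pair correlation and n.

    d = t * sqrt(2 (1 - r) / n); corrects the paired t for the correlation
    between the two measures so that d is on the original (between-scores)
    metric.
    """
    return float(t * np.sqrt(2.0 * (1.0 - r) / n))


def group_level_comparison(pair: PairComparison, r_a: float, r_b: float) -> GroupComparison:
    """Paired t test, Dunlap-corrected d, and (dis)attenuated correlation."""
    if pair.n < 3:
        raise ValueError("need n >= 3")
    a = pair.table["iq_a"].to_numpy(float)
    b = pair.table["iq_b"].to_numpy(float)
    r = float(np.corrcoef(a, b)[0, 1])
    d_var = (a - b).var(ddof=1)
    if d_var == 0:
        t_stat, p = float("nan"), float("nan")
        d = 0.0
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p = float(res.statistic), float(res.pvalue)
        d = paired_cohens_d(t_stat, r, pair.n)
    return GroupComparison(
        t=t_stat,
        df=pair.n - 1,
        p=p,
        d=d,
        r=r,
        r_corr=disattenuate(r, r_a, r_b),
        n=pair.n,
    )


def extremity_ratio(k: int, mean_rho: float) -> float:
    """How much more extreme a k-part composite is than its mean component.

    For a subject whose standardized component scores all sit z SDs from the
    mean, the standardized composite sits z * sqrt(k / (1 + (k-1) rho))
    SDs out: averaging cancels specific variance, so the composite grows
    more extreme the more (and the less correlated) its parts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    denom = 1.0 + (k - 1) * mean_rho
    if denom <= 0:
        raise ValueError(f"mean intercorrelation {mean_rho} makes composite variance <= 0")
    if mean_rho > 1:
        raise ValueError("mean intercorrelation cannot exceed 1")
    return float(np.sqrt(k / denom))
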