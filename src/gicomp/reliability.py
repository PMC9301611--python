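"""Classical-test-theory reliability algebra.

Cronbach's alpha, composite reliability from component reliabilities and
covariances (the textbook linear-combination formula: one minus the ratio of
summed component error variances to composite variance), age- and
IQ-group-specific coefficients, and the correction for attenuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .battery import BatteryConfig, NormTable, assign_iq_group, compute_composite_iqs

Band = tuple[float, float]


def _valid_coefficient(alpha: float | None) -> float | None:
    """Clamp an estimated coefficient into (0, 1] for CI use.

    Sample alphas can exceed 1 slightly (unequal component variances plus
    sampling noise); a non-positive estimate is treated as unavailable.
    """
    if alpha is None or alpha <= 0:
        return None
    return min(alpha, 1.0)


def cronbach_alpha(score_matrix) -> float:
    """Cronbach's alpha of a subjects x components score matrix.

    alpha = k/(k-1) * (1 - sum(var_j) / var_total), sample variances (n-1).
    Requires >= 2 components, >= 3 subjects and nonzero total variance.
    """
    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 components")
    if x.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    if np.isnan(x).any():
        x = x[~np.isnan(x).any(axis=1)]
        if x.shape[0] < 3:
            raise ValueError("fewer than 3 complete subjects")
    k = x.shape[1]
    var_total = x.sum(axis=1).var(ddof=1)
    if var_total <= 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - x.var(axis=0, ddof=1).sum() / var_total))


def composite_reliability(
    component_reliabilities: Sequence[float], component_covariances
) -> float:
    """Reliability of a unit-weighted composite from its components.

    r_C = 1 - sum_j sigma_j^2 (1 - r_j) / sigma_C^2, where sigma_C^2 is the
    sum over the full component covariance matrix.  For standardized
    components with equal r and equal intercorrelation rho this reduces to
    the Spearman-Brown stepped-up value k*r / (1 + (k-1)*r) when rho = r.
    """
    r = np.asarray(component_reliabilities, dtype=float)
    cov = np.atleast_2d(np.asarray(component_covariances, dtype=float))
    if cov.shape[0] != cov.shape[1] or cov.shape[0] != len(r):
        raise ValueError("covariance matrix shape must match the number of components")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    diag = np.diag(cov)
    if (diag <= 0).any():
        raise ValueError("component variances must be positive")
    var_c = float(cov.sum())
    if var_c <= 0:
        raise ValueError("composite variance is non-positive")
    return float(1.0 - np.sum(diag * (1.0 - r)) / var_c)


def disattenuate(r: float, r_a: float, r_b: float) -> float:
    """Correlation corrected for unreliability of both measures.

    r_corr = r / sqrt(r_a * r_b), capped at +/-1 with a warning when the
    correction overshoots.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if r_a <= 0 or r_b <= 0 or r_a > 1 or r_b > 1:
        raise ValueError("reliabilities must be in (0, 1]")
    corrected = r / np.sqrt(r_a * r_b)
    if abs(corrected) > 1.0:
        warnings.warn(
            f"disattenuated correlation {corrected:.4f} exceeds |1|; capped", stacklevel=2
        )
        corrected = float(np.sign(corrected))
    return float(corrected)


@dataclass
class ReliabilityLookup:
    """Reliability coefficients per composite, sliced four ways.

    ``overall`` and ``retest`` are keyed by composite name; ``by_age`` by
    (composite, age band); ``by_age_iq`` by (composite, age band, 3-level IQ
    group).  A missing or None entry means the cell is explicitly
    unavailable (e.g. too few subjects), never silently absent.  Accepts
    hand-entered published coefficients as well as cohort-estimated ones.
    """

    overall: dict[str, float] = field(default_factory=dict)
    by_age: dict[tuple[str, Band], float | None] = field(default_factory=dict)
    by_age_iq: dict[tuple[str, Band, str], float | None] = field(default_factory=dict)
    retest: dict[str, float | None] = field(default_factory=dict)
    min_cell: int = 30

    def get(
        self,
        kind: str,
        composite: str,
        band: Band | None = None,
        iq_group: str | None = None,
    ) -> float | None:
        """Coefficient for a criterion kind, or None if unavailable."""
        if kind in ("overall", "CI_overall", "NomCI"):
            return self.overall.get(composite)
        if kind in ("age", "CI_age"):
            return self.by_age.get((composite, tuple(band)))
        if kind in ("age_iq", "CI_ageIQ"):
            return self.by_age_iq.get((composite, tuple(band), iq_group))
        if kind in ("retest", "CI_rtt"):
            return self.retest.get(composite)
        raise ValueError(f"unknown reliability kind {kind!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp, v in self.overall.items():
            rows.append({"composite": comp, "kind": "overall", "value": v})
        for comp, v in self.retest.items():
            rows.append({"composite": comp, "kind": "retest", "value": v})
        for (comp, band), v in self.by_age.items():
            rows.append({"composite": comp, "kind": "age",
                         "band_lower": band[0], "band_upper": band[1], "value": v})
        for (comp, band, grp), v in self.by_age_iq.items():
            rows.append({"composite": comp, "kind": "age_iq", "band_lower": band[0],
                         "band_upper": band[1], "iq_group": grp, "value": v})
        return pd.DataFrame(rows)


def groupwise_reliability(
    cohort: pd.DataFrame,
    composite: str,
    battery: BatteryConfig,
    norms: NormTable,
    iq_scheme: str = "3",
    min_cell: int = 30,
) -> dict[tuple[Band, str], float | None]:
    """Per (age band x IQ group) Cronbach's alpha over a composite's members.

    Cells are indexed by the composite's *own* observed IQ.  Cells with
    fewer than ``min_cell`` complete subjects, or where alpha cannot be
    computed (zero variance), are flagged unavailable (None) without
    aborting the remaining cells.
    """
    comp = battery.composite(composite)
    iqs = compute_composite_iqs(cohort, battery, norms, [composite])[composite]
    bands = pd.Series([battery.age_band_of(a) for a in cohort["age"]], index=cohort.index)
    groups = iqs.map(lambda q: assign_iq_group(int(q), iq_scheme))
    labels = ("below_average", "average", "above_average") if iq_scheme in ("3", 3) else None
    if labels is None:
        labels = tuple(sorted(groups.unique()))
    out: dict[tuple[Band, str], float | None] = {}
    for band in battery.age_bands:
        for grp in labels:
            mask = ((bands == band) & (groups == grp)).to_numpy()
            sub = cohort.loc[mask, list(comp.members)].dropna()
            if len(sub) < min_cell:
                out[(band, grp)] = None
                continue
            try:
                out[(band, grp)] = _valid_coefficient(cronbach_alpha(sub.to_numpy()))
            except ValueError:
                out[(band, grp)] = None
    return out


def build_reliability_lookup(
    cohort: pd.DataFrame,
    battery: BatteryConfig,
    norms: NormTable,
    min_cell: int = 30,
) -> ReliabilityLookup:
    """Estimate a full ReliabilityLookup from a normed cohort.

    Overall and age-band coefficients are Cronbach's alphas over member
    subtests; age-x-IQ cells come from :func:`groupwise_reliability`;
    retest coefficients are taken from the battery configuration (they
    cannot be estimated from a single-session cohort).
    """
    lookup = ReliabilityLookup(min_cell=min_cell)
    bands = pd.Series([battery.age_band_of(a) for a in cohort["age"]], index=cohort.index)
    for comp in battery.composites:
        member_scores = cohort[list(comp.members)]
        lookup.overall[comp.name] = _valid_coefficient(
            cronbach_alpha(member_scores.dropna().to_numpy())
        )
        lookup.retest[comp.name] = comp.retest
        for band in battery.age_bands:
            sub = member_scores[(bands == band).to_numpy()].dropna()
            if len(sub) < min_cell:
                lookup.by_age[(comp.name, band)] = None
            else:
                try:
                    lookup.by_age[(comp.name, band)] = _valid_coefficient(
                        cronbach_alpha(sub.to_numpy())
                    )
                except ValueError:
                    lookup.by_age[(comp.name, band)] = None
        cells = groupwise_reliability(cohort, comp.name, battery, norms, min_cell=min_cell)
        for (band, grp), val in cells.items():
            lookup.by_age_iq[(comp.name, band, grp)] = val
    return lookup
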