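"""Declarative test-battery model and composite-score norming.

A battery is a set of subtests (each tapping one Cattell-Horn-Carroll broad
ability, with a general-factor loading and a reliability) plus one or more
unit-weighted composites (general intelligence composites, GICs).  Composite
sums are normed within age bands to the IQ metric (mean 100, SD 15); subtest
scores live on the scaled-score metric (mean 10, SD 3).

This module also provides the nominal IQ categories used by category-based
comparability rules, the 3- and 6-level IQ groupings used for reliability
cells and rate breakdowns, and the content-overlap arithmetic for comparing
two composites' ability coverage.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval

#: CHC broad-ability codes accepted for subtests.
CHC_ABILITIES = ("Gf", "Gc", "Gsm", "Gv", "Glr", "Gs", "Gq")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf.

    Python's built-in ``round`` uses banker's rounding; IQ reporting rounds
    half-up (37.5 -> 38), so all score rounding funnels through here.
    """
    return int(math.floor(x + 0.5))


class NominalCategory(enum.IntEnum):
    """Ordered nominal IQ categories with inclusive integer ranges.

    lower_extreme <70, below_average 70-84, average 85-115,
    above_average 116-130, upper_extreme >130.
    """

    lower_extreme = 0
    below_average = 1
    average = 2
    above_average = 3
    upper_extreme = 4


# Inclusive integer bounds per category; open ends encoded with +/-inf.
_CATEGORY_BOUNDS: dict[NominalCategory, tuple[float, float]] = {
    NominalCategory.lower_extreme: (-math.inf, 69),
    NominalCategory.below_average: (70, 84),
    NominalCategory.average: (85, 115),
    NominalCategory.above_average: (116, 130),
    NominalCategory.upper_extreme: (131, math.inf),
}


def nominal_category(iq: int) -> NominalCategory:
    """Map an integer IQ to its nominal category."""
    for cat, (lo, hi) in _CATEGORY_BOUNDS.items():
        if lo <= iq <= hi:
            return cat
    raise AssertionError("category bounds are exhaustive")  # pragma: no cover


def interval_to_categories(interval: Interval) -> tuple[NominalCategory, ...]:
    """Contiguous run of nominal categories intersected by the interval.

    Bounds are rounded half-up to integers first, so e.g. the interval
    [112, 120] maps to (average, above_average).
    """
    lo = nominal_category(round_half_up(interval.lower))
    hi = nominal_category(round_half_up(interval.upper))
    return tuple(NominalCategory(v) for v in range(lo, hi + 1))


#: Labels of the 3-level IQ grouping (<85 / 85-115 / >115).
IQ_GROUPS_3 = ("below_average", "average", "above_average")
#: Labels of the 6-level IQ grouping.
IQ_GROUPS_6 = ("<70", "70-84", "85-99", "100-114", "115-129", ">=130")


def assign_iq_group(iq: int, scheme: str = "3") -> str:
    """Assign an integer IQ to a group of the 3- or 6-level scheme.

    3-level: <85 below_average, 85-115 average, >115 above_average.
    6-level: <70, 70-84, 85-99, 100-114, 115-129, >=130.
    """
    if scheme in ("3", 3):
        if iq < 85:
            return "below_average"
        if iq <= 115:
            return "average"
        return "above_average"
    if scheme in ("6", 6):
        if iq < 70:
            return "<70"
        if iq < 85:
            return "70-84"
        if iq < 100:
            return "85-99"
        if iq < 115:
            return "100-114"
        if iq < 130:
            return "115-129"
        return ">=130"
    raise ValueError(f"unknown IQ group scheme {scheme!r}; use '3' or '6'")


@dataclass(frozen=True)
class SubtestSpec:
    """One subtest: its broad ability, general-factor loading and reliability.

    ``loading`` is the standardized general-factor loading lambda_j in [0, 1];
    ``reliability`` the internal consistency r_j in (0, 1].  The common
    variance lambda_j**2 cannot exceed the true-score variance r_j.
    ``retest`` is an optional test-retest coefficient.
    """

    name: str
    ability: str
    loading: float
    reliability: float
    retest: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError(f"{self.name}: loading {self.loading} outside [0, 1]")
        if not 0.0 < self.reliability <= 1.0:
            raise ValueError(f"{self.name}: reliability {self.reliability} outside (0, 1]")
        if self.loading**2 > self.reliability + 1e-12:
            raise ValueError(
                f"{self.name}: loading^2 = {self.loading ** 2:.4f} exceeds "
                f"reliability {self.reliability} (common variance > true-score variance)"
            )
        if self.retest is not None and not 0.0 < self.retest <= 1.0:
            raise ValueError(f"{self.name}: retest {self.retest} outside (0, 1]")


@dataclass(frozen=True)
class CompositeSpec:
    """A unit-weighted composite (GIC) over named member subtests."""

    name: str
    members: tuple[str, ...]
    clip_range: tuple[int, int] = (55, 145)
    retest: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError(f"{self.name}: composite has no members")
        if not self.clip_range[0] < self.clip_range[1]:
            raise ValueError(f"{self.name}: clip_range {self.clip_range} not ordered")
        if self.retest is not None and not 0.0 < self.retest <= 1.0:
            raise ValueError(f"{self.name}: retest {self.retest} outside (0, 1]")

    @property
    def k(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class BatteryConfig:
    """A battery: subtests, composites and the age bands used for norming.

    Age bands are half-open [lower, upper) intervals in years, ordered,
    non-overlapping and exhaustive over the battery's age range; the last
    band additionally includes its upper endpoint.
    """

    name: str
    subtests: tuple[SubtestSpec, ...]
    composites: tuple[CompositeSpec, ...]
    age_bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subtests", tuple(self.subtests))
        object.__setattr__(self, "composites", tuple(self.composites))
        object.__setattr__(self, "age_bands", tuple(tuple(b) for b in self.age_bands))
        names = [s.name for s in self.subtests]
        if len(set(names)) != len(names):
            raise ValueError("duplicate subtest names")
        for comp in self.composites:
            missing = set(comp.members) - set(names)
            if missing:
                raise ValueError(f"{comp.name}: unknown member subtests {sorted(missing)}")
        for (lo, hi), (lo2, _hi2) in zip(self.age_bands, self.age_bands[1:]):
            if hi != lo2 or lo >= hi:
                raise ValueError("age bands must be ordered, contiguous and non-empty")

    @property
    def subtest_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.subtests)

    def subtest(self, name: str) -> SubtestSpec:
        for s in self.subtests:
            if s.name == name:
                return s
        raise KeyError(f"no subtest named {name!r}")

    def composite(self, name: str) -> CompositeSpec:
        for c in self.composites:
            if c.name == name:
                return c
        raise KeyError(f"no composite named {name!r}")

    def age_band_of(self, age: float) -> tuple[float, float]:
        """The band containing ``age`` (last band closed above)."""
        for i, (lo, hi) in enumerate(self.age_bands):
            if lo <= age < hi or (i == len(self.age_bands) - 1 and age == hi):
                return (lo, hi)
        raise ValueError(f"age {age} outside battery age range "
                         f"[{self.age_bands[0][0]}, {self.age_bands[-1][1]}]")

    def band_label(self, band: tuple[float, float]) -> str:
        return f"{band[0]:g}-{band[1]:g}"


class NormingError(ValueError):
    """Raised when a norm-table cell cannot be computed."""


@dataclass
class NormTable:
    """Per (composite, age band) mean/SD of the unit-weighted member-score sum.

    Built from a reference cohort; used to map composite sums onto the IQ
    metric (100 + 15 z).  ``cells`` maps (composite name, band) to
    (mean, sd, n).
    """

    cells: dict[tuple[str, tuple[float, float]], tuple[float, float, int]] = field(
        default_factory=dict
    )

    def cell(self, composite: str, band: tuple[float, float]) -> tuple[float, float, int]:
        key = (composite, tuple(band))
        if key not in self.cells:
            raise NormingError(f"no norm cell for composite {composite!r}, band {band}")
        return self.cells[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"composite": comp, "band_lower": band[0], "band_upper": band[1],
             "mean": mu, "sd": sd, "n": n}
            for (comp, band), (mu, sd, n) in self.cells.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NormTable":
        cells = {
            (r.composite, (float(r.band_lower), float(r.band_upper))):
                (float(r["mean"]), float(r.sd), int(r.n))
            for _, r in frame.iterrows()
        }
        return cls(cells)


def build_norm_table(cohort: pd.DataFrame, battery: BatteryConfig) -> NormTable:
    """Norm every composite within every age band of a reference cohort.

    The cohort needs an ``age`` column and one column per member subtest.
    Each cell requires >= 2 subjects with complete member scores and
    nonzero variance of the member-score sum.
    """
    table = NormTable()
    bands = pd.Series(
        [battery.age_band_of(a) for a in cohort["age"]], index=cohort.index
    )
    for comp in battery.composites:
        sums = cohort[list(comp.members)].sum(axis=1, skipna=False)
        for band in battery.age_bands:
            vals = sums[(bands == band).values].dropna()
            label = f"({comp.name}, {battery.band_label(band)})"
            if len(vals) < 2:
                raise NormingError(f"norm cell {label} has {len(vals)} subjects; need >= 2")
            mu, sd = float(vals.mean()), float(vals.std(ddof=1))
            if sd == 0.0:
                raise NormingError(f"norm cell {label} has zero variance")
            table.cells[(comp.name, band)] = (mu, sd, int(len(vals)))
    return table


def compute_composite_iq(
    scores: Mapping[str, float],
    composite: CompositeSpec,
    norms: NormTable,
    age: float,
    battery: BatteryConfig,
    clip: bool = True,
) -> int:
    """IQ of one subject on one composite: 100 + 15 z of the member-score sum.

    The result is rounded half-up to an integer and, by default, clipped to
    the composite's floor/ceiling range.  Missing member scores raise; no
    imputation is performed.
    """
    missing = [m for m in composite.members if m not in scores or pd.isna(scores[m])]
    if missing:
        raise ValueError(f"{composite.name}: missing member scores {missing}")
    s = float(sum(scores[m] for m in composite.members))
    mu, sd, _ = norms.cell(composite.name, battery.age_band_of(age))
    iq = round_half_up(100.0 + 15.0 * (s - mu) / sd)
    if clip:
        iq = min(max(iq, composite.clip_range[0]), composite.clip_range[1])
    return iq


def compute_composite_iqs(
    cohort: pd.DataFrame,
    battery: BatteryConfig,
    norms: NormTable,
    composites: Sequence[str] | None = None,
    clip: bool = True,
) -> pd.DataFrame:
    """Vectorized composite IQs for a whole cohort; one column per composite."""
    names = composites if composites is not None else [c.name for c in battery.composites]
    bands = pd.Series([battery.age_band_of(a) for a in cohort["age"]], index=cohort.index)
    out = pd.DataFrame(index=cohort.index)
    for name in names:
        comp = battery.composite(name)
        sums = cohort[list(comp.members)].sum(axis=1, skipna=False).to_numpy(float)
        mu = np.empty(len(cohort))
        sd = np.empty(len(cohort))
        for band in battery.age_bands:
            mask = (bands == band).to_numpy()
            if mask.any():
                m, s, _ = norms.cell(name, band)
                mu[mask], sd[mask] = m, s
        iq = np.floor(100.0 + 15.0 * (sums - mu) / sd + 0.5)
        if clip:
            iq = np.clip(iq, comp.clip_range[0], comp.clip_range[1])
        out[name] = iq.astype(int)
    return out


def content_overlap(battery: BatteryConfig, a: CompositeSpec | str, b: CompositeSpec | str) -> int:
    """Percent content overlap of two composites' broad-ability coverage.

    The number of subtests (over both composites) tapping an ability tapped
    by *both* composites, divided by the total number of subtests over both,
    times 100, rounded half-up.
    """
    if isinstance(a, str):
        a = battery.composite(a)
    if isinstance(b, str):
        b = battery.composite(b)
    abilities_a = {battery.subtest(m).ability for m in a.members}
    abilities_b = {battery.subtest(m).ability for m in b.members}
    shared = abilities_a & abilities_b
    n_shared = sum(battery.subtest(m).ability in shared for m in a.members) + sum(
        battery.subtest(m).ability in shared for m in b.members
    )
    return round_half_up(100.0 * n_shared / (a.k + b.k))


def gpa(grades: Mapping[str, Iterable[float]] | Iterable[float]) -> float | dict[str, float]:
    """Grade point average on the Swiss 1-6 scale.

    Accepts either one subject's grades (iterable) or a mapping
    subject -> grades; missing grades are ignored, and a subject with no
    grades gets NaN, never zero.
    """
    if isinstance(grades, Mapping):
        return {subj: gpa(vals) for subj, vals in grades.items()}
    vals = [g for g in grades if g is not None and not pd.isna(g)]
    for g in vals:
        if not 1.0 <= g <= 6.0:
            raise ValueError(f"grade {g} outside the 1-6 scale")
    return float(np.mean(vals)) if vals else float("nan")
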