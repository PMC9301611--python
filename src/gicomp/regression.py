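"""External-validity regressions and gamma-GLM modelling of IQ differences.

Two analysis families live here.  First, simple standardized regressions of
school grades on composite IQs, compared across composites with the
proportion-overlap rule for 95% CIs of betas (two betas differ if their CIs
overlap by 50% or less of the average CI arm), including the median-split
re-analysis on small- vs large-difference subsamples.  Second, gamma
generalized linear models with a log link for absolute IQ differences —
right-skewed, nonnegative, continuous — with all predictors standardized by
dividing by two standard deviations so binary and continuous coefficients are
size-comparable, and likelihood-ratio tests for overall model significance.

The GLM mean structure is fitted by iteratively reweighted least squares
(statsmodels); the gamma shape parameter is then profiled out by maximum
likelihood so that log-likelihoods (and hence LRTs) are genuine ML values
rather than moment-based approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .comparability import PairComparison
from .intervals import Interval, intersection_length


@dataclass(frozen=True)
class RegressionFit:
    """Standardized simple regression: beta (= Pearson r), its CI, and R^2."""

    beta: float
    ci: Interval
    r2: float
    n: int
    outcome: str = "y"
    predictor: str = "x"


def fit_grade_regression(
    outcome, predictor, outcome_name: str = "grade", predictor_name: str = "iq"
) -> RegressionFit:
    """Least-squares regression of grades on an IQ, both z-scored.

    On standardized variables the slope equals the Pearson correlation and
    R^2 its square.  The beta CI uses the t distribution with n - 2 df on
    the standardized slope's standard error sqrt((1 - r^2) / (n - 2)).
    Pairs with a missing value are dropped.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    n = len(y)
    if n < 10:
        raise ValueError(f"need n >= 10 complete pairs, got {n}")
    if y.std(ddof=1) == 0 or x.std(ddof=1) == 0:
        raise ValueError("constant outcome or predictor")
    beta = float(np.corrcoef(x, y)[0, 1])
    se = np.sqrt(max(0.0, 1.0 - beta**2) / (n - 2))
    tcrit = stats.t.ppf(0.975, n - 2)
    return RegressionFit(
        beta=beta,
        ci=Interval(beta - tcrit * se, beta + tcrit * se),
        r2=beta**2,
        n=n,
        outcome=outcome_name,
        predictor=predictor_name,
    )


def beta_ci_overlap_fraction(ci_a: Interval, ci_b: Interval) -> tuple[float, bool]:
    """Proportion overlap of two beta CIs and the 50%-rule difference flag.

    fraction = length of the intersection divided by the average half-width
    (arm) of the two CIs, floored at 0 and capped at 2.  The two betas are
    flagged as significantly different iff the fraction is <= 0.5.
    """
    mean_half_width = (ci_a.width + ci_b.width) / 4.0
    if mean_half_width == 0:
        raise ValueError("both intervals have zero width; overlap fraction undefined")
    frac = min(2.0, max(0.0, intersection_length(ci_a, ci_b) / mean_half_width))
    return frac, frac <= 0.5


@dataclass(frozen=True)
class MedianSplit:
    """Subjects split at the median absolute IQ difference."""

    small: pd.DataFrame  # abs_diff strictly below the median
    large: pd.DataFrame  # abs_diff at or above the median
    median: float

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.small), len(self.large)


def median_split(pair: PairComparison) -> MedianSplit:
    """Split a pair's subjects into below-median and at-or-above-median |D|."""
    med = float(pair.abs_diff.median())
    below = pair.table[pair.abs_diff < med]
    above = pair.table[pair.abs_diff >= med]
    return MedianSplit(small=below, large=above, median=med)


def two_sd_standardize(design: pd.DataFrame) -> pd.DataFrame:
    """Divide every predictor column by twice its (population) SD.

    Applies to continuous and binary columns alike, so coefficients are
    directly size-comparable; an exactly balanced binary indicator has SD
    0.5 and is left unchanged.  Continuous (non-binary) columns are centered
    at their mean before the division, so that with interactions present a
    main effect is read at the mean of the interacting covariate; binary
    indicators keep their 0 reference level.  The result carries a
    provenance flag and the transform refuses to run twice (it is not
    idempotent).  Interaction columns should be built *after* standardizing
    the main effects.
    """
    if design.attrs.get("two_sd_standardized"):
        raise ValueError("design is already 2SD-standardized; refusing to standardize twice")
    out = design.copy()
    for col in out.columns:
        vals = out[col]
        sd = float(vals.std(ddof=0))
        if sd == 0:
            raise ValueError(f"predictor {col!r} is constant (zero SD)")
        if not set(np.unique(vals)) <= {0.0, 1.0}:
            vals = vals - vals.mean()
        out[col] = vals / (2.0 * sd)
    out.attrs["two_sd_standardized"] = True
    return out


@dataclass
class GlmFit:
    """A fitted gamma GLM with log link.

    ``params``/``bse``/``pvalues`` are indexed by design column (plus
    ``const``); ``shape`` is the ML gamma shape (dispersion = 1/shape);
    ``llf`` the profile-ML log-likelihood; Wald p-values use the ML
    dispersion.  ``y`` is retained so nested models can be checked.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    shape: float
    llf: float
    deviance: float
    n: int
    exog_names: tuple[str, ...]
    y: np.ndarray = field(repr=False, default=None)
    n_zeros_adjusted: int = 0


def _gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """ML gamma shape given fitted means: solves log(a) - digamma(a) = m."""
    ratio = y / mu
    m = float(np.mean(ratio - np.log(ratio)) - 1.0)
    if m <= 1e-12:
        return 1e8  # essentially degenerate (y == mu everywhere)

    def f(a: float) -> float:
        return np.log(a) - special.digamma(a) - m

    return float(optimize.brentq(f, 1e-8, 1e10, xtol=1e-12, rtol=1e-14))


def _gamma_llf(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    return float(stats.gamma.logpdf(y, a=shape, scale=mu / shape).sum())


def fit_gamma_glm(
    y,
    design: pd.DataFrame | None = None,
    zero_rule: str | None = "half-point",
    add_intercept: bool = True,
    maxiter: int = 100,
) -> GlmFit:
    """Gamma GLM with log link for absolute IQ differences.

    The mean is fitted by IRLS; the shape by profile maximum likelihood.
    Exact zeros (possible on the integer IQ scale) are replaced by 0.5 IQ
    points — the smallest half-unit — under the default ``zero_rule``;
    with ``zero_rule=None`` zeros raise.  ``design`` may be None for an
    intercept-only model; a rank-deficient design raises.
    """
    y = np.asarray(y, dtype=float).copy()
    if np.isnan(y).any():
        raise ValueError("y contains missing values")
    if (y < 0).any():
        raise ValueError("y must be nonnegative")
    if len(y) and np.ptp(y) == 0:
        raise ValueError("response is constant; a gamma GLM cannot be fitted")
    n_zeros = int((y == 0).sum())
    if n_zeros:
        if zero_rule == "half-point":
            y[y == 0] = 0.5
        else:
            raise ValueError(
                f"{n_zeros} zero responses present and zero handling disabled"
            )

    if design is None:
        design = pd.DataFrame(index=pd.RangeIndex(len(y)))
    x = design.copy()
    if add_intercept and "const" not in x.columns:
        x.insert(0, "const", 1.0)
    if len(x) != len(y):
        raise ValueError("design and response lengths differ")
    xm = x.to_numpy(float)
    if np.linalg.matrix_rank(xm) < xm.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear or duplicated columns)")
    if xm.shape[0] <= xm.shape[1]:
        raise ValueError("need more observations than parameters")

    model = sm.GLM(y, xm, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(maxiter=maxiter)
    if not res.converged:
        raise RuntimeError(
            f"gamma GLM did not converge in {maxiter} IRLS iterations; "
            f"final deviance {res.deviance:.4g}"
        )
    mu = res.mu
    shape = _gamma_shape_mle(y, mu)
    llf = _gamma_llf(y, mu, shape)
    # Wald inference with the ML dispersion (1/shape) instead of the
    # Pearson moment estimate that IRLS reports by default.
    cov = res.cov_params() * ((1.0 / shape) / res.scale)
    bse = np.sqrt(np.diag(cov))
    zvals = res.params / bse
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    names = list(x.columns)
    return GlmFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        shape=shape,
        llf=llf,
        deviance=float(res.deviance),
        n=len(y),
        exog_names=tuple(names),
        y=y,
        n_zeros_adjusted=n_zeros,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float


def likelihood_ratio_test(full: GlmFit, null: GlmFit) -> LRTResult:
    """LRT of a nested gamma GLM pair: 2 (ll_full - ll_null) ~ chi2(df).

    The null's design columns must be a subset of the full's, fitted to the
    same response.
    """
    if not set(null.exog_names) <= set(full.exog_names):
        raise ValueError("models are not nested (null has predictors the full model lacks)")
    if full.n != null.n or not np.allclose(full.y, null.y):
        raise ValueError("models were fitted to different responses")
    df = len(full.exog_names) - len(null.exog_names)
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, p=p)
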