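# Methods

## Scope and design

`gicomp` analyzes the *individual-level* comparability of general
intelligence composites (GICs) — unit-weighted sums of subtest scaled
scores normed to the IQ metric — within one battery.  The pipeline is:
age-band norming → integer composite IQs → intraindividual differences →
group-level agreement statistics → six interval-overlap comparability
criteria with IQ-group and age-group breakdowns → external-validity
regressions on school grades → gamma-GLM prediction of absolute
differences.  Real standardization samples are proprietary, so the package
includes a generator whose output has the statistical structure the
analysis assumes; all distributional tests run against it or against closed
forms.

## Score model and norming

Subtests live on the scaled-score metric (mean 10, SD 3); composites on the
IQ metric (mean 100, SD 15).  A norm table holds the mean and SD (n−1) of
each composite's member-score sum per age band, estimated from a reference
cohort; an IQ is `round_half_up(100 + 15 (S − μ_band)/σ_band)` clipped to
the composite's floor/ceiling range (default 55–145, configurable per
composite because published batteries truncate differently).  IQs are
rounded to integers *before* any downstream use — category assignment,
differences, CIs — because that is the score a practitioner sees; rounding
is half-up throughout (so a content overlap of 37.5% reports as 38).

Nominal categories are lower extreme (<70), below average (70–84), average
(85–115), above average (116–130), upper extreme (>130).  IQ groupings:
3-level (<85 / 85–115 / >115) for reliability cells, 6-level (<70 / 70–84 /
85–99 / 100–114 / 115–129 / ≥130) for rate breakdowns.  Rate breakdowns by
IQ use the composite with more subtests in the pair, matching the
convention of indexing a person's level by the longest available measure.

## True-score confidence intervals

For observed IQ `X` with reliability `r`: estimated true score
`T̂ = 100 + r(X − 100)` and standard error of estimate
`SE_E = 15 √(r(1−r))`; the CI is `T̂ ± z SE_E`.  Internally
`z₀.₉₅ = 1.959964` (the exact normal quantile); reported widths are
`round_half_up(2 z SE_E)`.  Both the exact and the rounded 1.96 quantile
give identical integer widths for every published overall coefficient
(.93–.99); the published retest-based widths for coefficients .89 and .86
are one point larger than the round-half-up of the printed values, which is
consistent with the sources rounding their coefficients for display but
not for computation — the package computes from the coefficient it is
given and does not reconcile this.  CI bounds stay unrounded for overlap
tests (the data sheets only round reported widths); overlap of closed
intervals counts touching endpoints.

## The six criteria

NomIQ: identical nominal categories.  CI_overall / CI_age / CI_ageIQ /
CI_rtt: overlap of the two true-score CIs built with, respectively, the
overall internal consistency, the age-band coefficient, the
age-by-IQ-group coefficient, and the retest coefficient.  NomCI:
intersection of the nominal-category runs spanned by the overall-coefficient
CIs (bounds rounded half-up before categorization).  Each composite uses
its own coefficient, and the age-by-IQ cell is indexed by that composite's
own observed IQ — the only score available when interpreting that
composite.  Subjects whose required coefficient cell is unavailable are
excluded from that criterion only, with counts reported; rates never drop
subjects silently.

## Reliability estimation

Cronbach's alpha (`k/(k−1)(1 − Σvar_j/var_total)`), composite reliability
from component reliabilities and covariances
(`1 − Σσ_j²(1−r_j)/σ_C²`, the linear-combination formula that reduces to
Spearman–Brown for parallel parts), and disattenuation
(`r/√(r_a r_b)`, capped at ±1 with a warning).  The lookup built from a
cohort uses alpha over member subtests uniformly — overall, per age band,
and per age × 3-level-IQ cell — with cells under `min_cell` (default 30)
flagged unavailable rather than estimated unstably; estimates above 1
(possible with unequal variances) are clamped to 1, non-positive ones
flagged unavailable.  Hand-entered published coefficients can be supplied
instead for reproduction runs.

Two properties of alpha matter for interpretation.  First, when subtests
carry specific variance (r_j > λ_j²), alpha over subtests is a strict
*lower bound* on composite reliability (measured .867 vs .965 true on the
demo battery), so CI-based criteria built from it are conservative — wide
intervals, high comparability rates.  Second, cells conditioned on the
composite's own IQ are range-restricted, which drives within-cell alphas
far below the overall value (e.g. 0.31–0.58 vs 0.87 on a homogeneous
simulated cohort); this mirrors the pattern in published age-and-IQ-specific
coefficients and is the intended behaviour, not an estimation artifact.

## The generator

`x_j = λ_j(g) g + √ψ_j s_j + √θ_j e_j` with `ψ_j = r_j − λ_j(g)²`,
`θ_j = 1 − r_j`; all latent draws standard normal.  SLODR (Spearman's law
of diminishing returns) is a linear attenuation of loadings above the mean
only, `λ_j(g) = λ_j (1 − δ max(0, g))` floored at 0, with specific variance
recomputed so subtest reliability is preserved; default `δ = 0` (off).
Ages are uniform over the battery range with no age trend in latent
ability (scores are norm-referenced within band).  Scores are mapped to
`10 + 3x`, rounded to integers by default (`discretize=False` disables
this for structural oracle tests, since rounding adds ~1/12 variance per
subtest and attenuates correlations by ~1%), and optionally
floored/ceilinged.  Grades use the Swiss 1–6 ladder in 0.5 steps:
`clip(round_to_half(4.5 + 0.8(γ g + √(1−γ²) ε)), 1, 6)`; anchor 4.5 and
spread 0.8 are arbitrary choices that keep simulated grades off the
bounds, and γ (default .5, in the range typical of intelligence–grade
correlations) is the generating validity.  Covariate defaults: sex .5,
AD(H)D .05, language (monolingual/bilingual/other) .80/.12/.08, university
education .30, participation rating N(10, 3) rounded; grade subsample
fraction .25, emulating parent-report coverage.  The default sample size
is 1 600, on the order of a single battery's standardization sample.

Latent `g` and the error-free subtest scores are retained in reserved
columns (`g`, `true_*`) for parameter-recovery and coverage tests; exports
drop them by default.  What the generator does *not* emulate: correlated
broad-ability factors beyond one general factor, age trends in ability,
non-normal trait distributions, item-level raw-score scaling, adaptive
routing, and retest sessions.  Passing tests therefore demonstrate the
correctness of the algebra and the pipeline under the stated model, not
the empirical comparability rates of any real battery.

## Regression analyses

Grade regressions are simple least squares on z-scored variables, so the
standardized beta equals the Pearson correlation and R² its square; beta
CIs use the t distribution with n−2 df.  Two betas are declared different
when their 95% CIs overlap by at most 50% of the average CI arm
(proportion-overlap convention; the average-arm denominator is used, the
shorter-arm variant is not).  The median split assigns `|D| <` median to
the small-difference subsample and `|D| ≥` median to the large one.

Gamma GLMs with log link model `|D|`: zeros (possible on the integer IQ
scale) are replaced by 0.5 IQ points — the smallest half-unit — with the
count reported.  The mean structure is fitted by IRLS; the gamma shape is
then profiled out by maximum likelihood (solving
`log α − ψ(α) = mean(y/μ − log(y/μ)) − 1` by bracketing), so
log-likelihoods and LRTs are genuine ML quantities; per-coefficient Wald
tests use the ML dispersion.  Predictors are standardized by twice their
(population-)SD so binary and continuous coefficients are size-comparable;
continuous predictors are additionally mean-centered (binaries keep their
0 reference), which makes main effects in the age-by-IQ-level interaction
model readable at the mean age rather than at age 0.  Interaction columns
are products of the standardized mains.  Constant predictors are dropped
with a log note; the transform refuses to run twice.

## Problem sizes and numerical choices

Structural oracles run at n = 100 000 (correlations and reliabilities match
population values within 0.01); CTT coverage at n = 100 000 with the
composite's realized reliability computed as corr(observed, true IQ)²
(94.9–95.1% across seeds); LRT calibration uses 2 000 null replicates of
n = 500 (4.5–5.7% across seeds); GLM recovery n = 5 000 (coefficients
within 0.02); the SLODR power check uses slope 0.15 at n = 5 000 over 40
replicates.  Brentq tolerances for the shape solve are 1e−12 absolute;
IRLS runs to statsmodels defaults with a 100-iteration cap and raises on
non-convergence.

## Known limitations

Alpha-based lookups make CI criteria conservative on synthetic data (see
above); retest coefficients cannot be estimated from a single-session
cohort and come from configuration; the equivalence-and-stability
coefficient and factor-analytic reliability (omega) are out of scope; no
multiple-testing correction is applied anywhere, matching the analysis the
package mirrors.
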