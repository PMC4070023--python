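# Methods

This note records the statistical model, the defaults of the synthetic
cohort generator, the numerical choices inside the REML engine and the
agreement statistics, and the design decisions taken where more than
one reasonable construction existed.

## Model

For pupil *i* attending school *s(i)* and living in neighbourhood
(LSOA) *n(i)*, the BMI standard-deviation score is modelled as

    z_i = x_i'β + u_{s(i)} + v_{n(i)} + e_i

with mutually independent `u ~ N(0, σ²_school)`, `v ~ N(0, σ²_LSOA)`
and `e ~ N(0, σ²_e)`. The two grouping factors are *crossed*: a school
draws pupils from several neighbourhoods and a neighbourhood feeds
several schools, so neither factor nests in the other. The fixed part
is either the intercept alone (the "null" model, used only to
decompose variance into intraclass correlations) or intercept +
ethnicity (four indicator contrasts against White-British) +
normalised deprivation (the "adjusted" model behind the Expected and
Value-added rankings). Cohorts are pooled without a cohort indicator
by default; `ModelSpec(cohort_indicator=True)` adds one.

BMI is standardised by the LMS method. The inverse transform is only
defined while `1 + L·S·z > 0`; both directions are computed through
`expm1`/`log1p` so they are exact through the `L → 0` limit.

### Expected residuals

A school's "expected residual" is operationalised as the empirical
BLUP of `u_s` at the REML variance estimates — the shrunken departure
of the school from its covariate-expected mean — with prediction
standard errors from the inverse mixed-model coefficient matrix.
Unshrunken per-school means of `y − Xβ̂` are also available
(`raw_school_residuals`) for users who prefer raw aggregation; all
rankings and tests default to the BLUP, which is the standard choice
for institutional comparisons because it accounts for school size.

### Value-added scores

The adjusted model is refitted separately to Reception and to Year 6
pupils; the value-added score is `BLUP_Year6 − BLUP_Reception`. Because
the two fits estimate their own variance ratios, their shrinkage
factors differ by sampling noise; the part of the year-specific school
effect common to both cohorts then leaks into the difference with an
essentially random sign and magnitude. This is a property of the
method itself, not of the implementation, and is one mechanism behind
the poor concordance of value-added rankings with anything else —
including themselves in other years.

## REML estimation

The restricted log-likelihood is profiled over σ²_e and maximised over
the log variance ratios `γ_f = σ²_f / σ²_e`. Each objective evaluation
reduces the sparse incidence matrices to dense cross-products once and
then costs a single Cholesky factorisation of the q×q mixed-model
block (q = schools + neighbourhoods, typically ≤ ~800). The search is
a Nelder–Mead simplex (xatol 1e-6) followed by up to three
finite-difference Newton polish steps (step h = 1e-4), which locate
the optimum to ~1e-10 in the variance components — the simplex alone
stalls at the objective's floating-point noise floor around 1e-8. On
balanced one-way designs the estimates agree with the closed-form
ANOVA estimators to 1e-8, and on crossed designs with `lme4`'s REML
fits to ~1e-6 relative.

Variance components are constrained non-negative: ratios collapsing
below 1e-9 are pinned to exactly zero and the factor is refitted out
of the model (its BLUPs and their SEs are then exactly zero). Fixed
effects are the GLS solution at the estimated variances, with 95%
normal-theory intervals; rank deficiency of the fixed design raises an
error naming the aliased column; ethnicity categories absent from a
subset simply drop their indicator. Rows with missing values in any
model variable are deleted listwise and counted in the fit summary.

## Rankings

Scores are ranked ascending (rank 1 = lowest mean weight status); ties
share averaged ranks so rank-based agreement statistics remain well
defined. The minimum school size for inclusion defaults to 1 — no
exclusion — and is configurable; filtering occurs after scoring, so it
can never reorder the retained schools. Schools lacking pupils in
either cohort are excluded from the value-added table (logged).

## Agreement and tracking statistics

Lin's concordance `ρc = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²)` is computed
with population (1/n) moments; confidence intervals and the ρc = 0
test use the inverse-hyperbolic-tangent transform with Lin's corrected
asymptotic variance (Monte-Carlo coverage of the 95% interval under
bivariate normal sampling is 0.94–0.96 in the test suite). Agreement
defaults to *rank* vectors, since league tables are compared as
rankings; `use="score"` switches to the score scale. Two pandas Series
are paired by school index, never by position.

Quintiles split each year's ranking into five contiguous groups with
sizes as equal as possible (remainder to the earliest groups). The
tracking coefficient treats the years as interchangeable raters of
each school's quintile and computes the Fleiss multi-rater kappa, with
a p-value from its large-sample variance under the no-agreement null;
schools absent from any year are dropped listwise (logged). Under
independent uniform labels (300 schools × 5 years) the kappa is
centred on zero with ~5% type-I error, and the proportion of schools
constant in quintile matches the analytic (1/5)⁴. For two years the
statistic reduces to the two-rater chance-corrected coefficient
(Scott's π). No multiplicity adjustment is applied to the agreement
tables; significance flags use α = 0.05 two-sided.

## Synthetic cohort generator

The generator emulates a single-local-authority NCMP extract as repeated
cross-sections — new pupils every year — with defaults frozen to the
published sample description:

| parameter | default | rationale |
|---|---|---|
| schools / neighbourhoods | 300 / 500 | study scale |
| pupils per school per cohort | Poisson(19) | ~11.5k pupils/year over two cohorts |
| σ²_school, σ²_LSOA, σ²_e | 0.01874, 0.00551, 1.07825 | shares 0.017 / 0.005 / 0.978 of a total variance 1.1025 (SD 1.05) |
| deprivation effect β_IMD | 0.44 | BMI-SDS between least- and most-deprived areas |
| ethnicity frequencies | 95.6 / 2.1 / 0.5 / 1.2 / 0.6 % | five collapsed categories |
| ethnicity offsets | 0, 0.04, −0.07, −0.04, −0.16 | small compositional effects |
| deprivation distribution | Beta(3.5, 15) per LSOA | quartiles 0.12 / 0.18 / 0.24 |
| cohort mean BMI-SDS | 0.35 (Reception), 0.45 (Year 6) | high-normal pooled mean ~0.40 |
| persistence ρ | 0.5 | AR(1) correlation of school effects between consecutive years; at the default ICC this yields lag-1 between-year ranking concordances of ~0.2, the magnitude seen in real league tables |
| cohort-specific school effect SD | 0 | no true value-added signal by default; raise to inject one |

Neighbourhood effects and deprivation are fixed properties of the
LSOA, constant across years; deprivation is assigned at LSOA level so
all pupils from one neighbourhood share a value. Covariates are
centred inside the generator (deprivation about its Beta mean,
ethnicity indicators about their frequencies), so the configured
cohort means are the marginal means of the generated z-scores. True
z-scores are clipped at ±4.4, just inside the invertible range of the
bundled reference over ages 4–12 (affects ~5 in 10⁵ draws). School ×
neighbourhood catchments are built on a circle from nearest-neighbour
links, with consecutive schools sharing one LSOA so the incidence
graph is a single connected component — genuinely crossed, never
block-nested.

The bundled LMS reference is *synthetic*: smooth plausible L/M/S
curves over ages 3–14 (median dipping at the adiposity rebound, spread
and left-skew increasing with age). It is not the UK 1990 reference;
real tables can be supplied as CSV (`sex,age,L,M,S`). Age
interpolation is linear between knots, exact at knots, with a hard
error outside the covered range — silent extrapolation would corrupt
z-scores.

### What the generator does not emulate

Opt-outs and non-response, home/private education, measurement error
in height and weight, within-year migration, correlated school and
neighbourhood covariate composition beyond the catchment structure,
and secular drift in the BMI distribution. Passing tests therefore
show that the *pipeline* recovers what it should under the stated
model; they do not certify any particular substantive claim about real
schools.

## Problem sizes used in the test suite

Routine tests run on a reduced panel (50 schools, 3 years, ~1.4k
pupils/year). The parameter-recovery study uses 100 single-year panels
at full study scale; the mechanism test uses two-year panels at full
scale; the kappa calibration uses 500 replicates of 300 × 5 label
matrices. The acceptance script runs the complete 5-year, 300-school
pipeline.

## Known limitations

- Two crossed factors only; no random slopes, no non-normal responses.
- The REML covariance of the fixed effects is the asymptotic GLS one;
  no small-sample (Kenward–Roger-type) correction.
- The value-added construction inherits the instability discussed
  above; the package reports it honestly rather than smoothing it.
- Tracking kappa treats quintiles as nominal categories (unweighted);
  near-misses count as full disagreement.
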