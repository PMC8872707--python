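# Methods

`countydid` implements a quasi-experimental analysis pipeline for the effect
of a county-level program (federal funding for comprehensive sex education)
on county teen birth rates, together with a synthetic data-generating
process used to validate every estimator against known ground truth.

## Outcome and panel construction

The outcome for county *i*, state *j*, year *t* is `log(1 + R_ijt)`, where
`R` is births per 1,000 women aged 14–19 (pooled over single years of age by
default; an age-specific mode stacks one row per age with the same
right-hand side). Adding 1 inside the log keeps zero-rate county-years in
the sample and makes treatment coefficients roughly readable as percent
changes, exactly via `100·(exp(b) − 1)`.

Treatment is a binary funding indicator **lagged one year**: a conception
affected by programming in the funding year is carried to term the
following year. All time-varying covariates (distance to the nearest
abortion provider; unemployment, median household income, poverty; percent
of teen women aged 16–19; percent White, Black, Hispanic) enter with the
same one-year lag. The provider distance is observed only in 2000, 2011 and
2014; it is linearly interpolated between observation years and linearly
extrapolated outside them using the slope of the nearest observed segment.

Counties are excluded by five ordered rules (a county failing several is
attributed to the first, making the report deterministic): (1) any year of
zero teen female population or a flagged reporting-area change; (2) prior
abstinence-only program funding; (3) a missing year in any time-varying
covariate after interpolation; (4) funding outside the two main award
cohorts; (5) configured excluded states. Filters are idempotent.

## Regression models

Three nested two-way fixed-effects specifications:

1. `log(1+R) ~ treat_{t-1} + county FE + state-year FE`
2. adds the lagged covariates;
3. adds county-specific linear time trends.

State-year fixed effects (one intercept per state × year cell) absorb any
statewide annual shock, e.g. a state policy change; county trends absorb
smooth heterogeneous trajectories. Fixed effects are absorbed by
alternating-projection demeaning (county means or per-county {1, t}
projections, then state-year means) iterated until the largest within-sweep
update falls below `1e-10` relative to the data scale; this reproduces full
dummy-variable OLS, which the tests verify on small instances to `1e-8`.
Perfectly collinear columns are dropped by a greedy left-to-right rank
filter (deterministic "first kept" order; the treatment column is first and
an error is raised if it is absorbed). Inference is the CR1 cluster-robust
sandwich (clusters = counties, correction `G/(G−1)·(N−1)/(N−K)` with K
counting absorbed coefficients analytically) and `t(G−1)` critical values.
Saturated designs with no residual degrees of freedom skip the correction
with a warning. Singleton fixed-effect groups are retained.

## Group-time ATT estimation

Because adoption is staggered (cohorts first funded in 2010 and 2015), TWFE
coefficients are not ATTs. For cohort *g* (indexed by its first *lagged*
treatment year, funding year + 1) and year *t ≥ g*:

    ATT(g,t) = E[Y_t − Y_{g−1} | G = g] − E[Y_t − Y_{g−1} | never treated]

The comparison group is **never-treated counties only**, matching a design
in which prior abstinence-funded counties are excluded so controls are
never-funded throughout. Pre-treatment cells (*t < g*) use a varying base
period — the year-on-year change *t−1 → t* — and serve purely as
parallel-trend diagnostics. Anticipation is assumed absent beyond the
built-in one-year lag.

The conditional variant is doubly robust: an OLS outcome-regression model
of the never-treated outcome change on base-period covariates, combined
with Hajek-normalized inverse-probability weights from a logistic
group-membership score on the same covariates (pure outcome-regression and
pure IPW variants are selectable). It is consistent if either nuisance
model is correct; the tests verify this under each misspecification
pattern. Covariates are standardized within the estimation subsample and
collinear columns dropped before fitting; any estimated propensity within
`1e-6` of 1 raises an overlap error naming the counties. Influence
functions include the delta-method corrections for both estimated nuisance
models, so analytic and bootstrap standard errors account for nuisance
estimation.

**Aggregation.** The overall ATT weights each cohort's time-averaged
post-treatment ATT(g,t) by its treated-county share (cell-count weighting
is selectable); event-time *e* aggregates ATT(g, g+e) across cohorts
observing *e* with the same weights. Weight estimation contributes its own
influence-function term. Standard errors are `‖ψ‖/N` over county-level
influence contributions.

**Multiplier bootstrap.** County-level influence sums are perturbed by
Rademacher signs (default 999 draws, seeded). Pointwise SEs use the
bootstrap interquartile range scaled by the normal IQR (robust to heavy
tails); the simultaneous band multiplies the pointwise SE by the 95%
quantile of the maximum absolute studentized deviation across event times.
Statistics with identically zero influence get SE 0 and are excluded from
the max. Fewer than 20 clusters triggers a warning.

**Pre-trend Wald test.** `a' V⁻¹ a` with V from the influence functions,
chi-square with df = number of cells tested; a singular V falls back to the
pseudo-inverse with df = rank and a warning. The pipeline tests the
cohort-aggregated event-study estimates at event times −5…−1 rather than
every raw (g,t) pre cell: with cohorts of a few dozen counties the joint
covariance of 30+ pre cells cannot be estimated stably enough to invert
(the full-cell statistic rejects a true null most of the time), while the
aggregated near-adoption window — matching the five-year post horizon the
event study reports — is well calibrated. The window is configurable
(`wald_pre_window`, `None` tests all aggregated pre event times).

## Synthetic data-generating process

The generator emulates the statistical structure the estimators assume:

    log(1 + R_it) = b0 + a_i + phi_{s(i),t} + d_i·(t − t0)
                    + x_{i,t−1}'beta + tau(e_it)·1{treated} + eps_it

with county intercepts `a_i ~ N(0, 0.4²)`, state-year shocks
`phi ~ N(0, 0.05²)`, county trend slopes `d_i ~ N(0, 0.004²)` per year,
idiosyncratic noise `eps ~ N(0, 0.07²)`, and baseline rate 40 births per
1,000 (the scale of US teen birth rates early in the period). The noise
scale was set so that event-time standard errors at the design's cohort
sizes are on the order of a 3-percentage-point CI half-width. The effect
path `tau(e)` defaults to a linear ramp from −0.015 at event time 0 to
−0.07 at event time 4, held flat at −0.07 for the later event times the
panel realizes (a modeling choice; nothing is asserted about effects beyond
the fifth year). Covariates are AR(1) county series (rho 0.85) around
state-level means at realistic levels; the provider distance is blanked
outside its observation years (unless fewer than two fall inside the panel,
in which case it stays fully observed so short test panels remain usable).
Populations by single age are drawn once per county (lognormal, median
~245 women per age) and perturbed by 2% annual multiplicative noise.

The full-scale default reproduces the target design: 2,927 counties in 49
states (distributed round-robin, since 2,927 is prime), 1996–2017, cohorts
of 36 counties funded from 2010 and 19 more from 2015 (55 total).
Treatment is absorbing. In the default `gaussian_rate` mode births are
expected counts (possibly fractional), which preserves the rate exactly
and makes noiseless recovery tests exact; `poisson_births` draws integer
counts per age for count-noise robustness checks. `adoption_trend_bias`
makes funding adoption select counties on declining trends, creating the
confounding that separates the trend-robust estimators from Model 1.

Ground truth records the event-time effects and two overall ATT estimands:
the treated-cell-weighted mean (what a cell-weighted aggregation targets)
and the cohort-size-weighted mean (the default aggregation's estimand);
validation compares each estimator to its matching estimand.

**What the generator does not emulate:** real geography (no FIPS codes, no
spatial correlation beyond state-year shocks), migration or age-structure
dynamics, serially correlated idiosyncratic errors, reporting artifacts,
or abortion/pregnancy as intermediate outcomes. Passing recovery tests
shows the estimators are correct for data satisfying their assumptions,
not that those assumptions hold in any real natality panel.

## Calibration study sizes

Monte Carlo calibration runs use 300 counties in 10 states over the full
22-year window, keeping the absolute cohort sizes (36 and 19) of the
target design so the treated-sample information per estimator matches the
real setting while replication is cheap. Calibration checks use 200
replications; generator seeds are `seed + rep`, bootstrap seeds offset by
500,003, all below 2³¹.

## Known limitations

- The conditional estimator requires covariate overlap; tiny cohorts with
  extreme covariates can fail the propensity fit or the overlap check.
- The pre-trend Wald test's default window is a finite-sample compromise;
  with thousands of treated counties a wider window would be usable.
- County-level clustering ignores within-state cross-county dependence
  beyond what state-year shocks contribute to the point estimates; this
  mirrors the inference convention of the target design.
- The CR1 absorbed-coefficient count is analytic (counties nested in
  states) and approximate for pathological fixed-effect graphs; it only
  scales the small-sample correction.
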