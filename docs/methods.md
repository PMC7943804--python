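# Methods

## Model and estimation

The analysis targets the association between rare, acutely timed
tropical-cyclone wind exposures and daily cause-specific
hospitalization counts on a county-day panel. Days are grouped into
strata sharing a county and a calendar (month, day) across years, so
that within-stratum contrasts compare the same place at the same point
in the seasonal cycle. Conditioning on the stratum totals removes all
confounding that is constant within a stratum — county-level
characteristics and seasonality — analogous to a time-stratified
case-crossover design.

We key strata on the calendar pair (month, day-of-month) rather than
ordinal day-of-year so that, e.g., Sep-15 matches Sep-15 in leap and
non-leap years alike; Feb 29 forms its own sparse stratum containing
only leap-year days. Strata whose counts are all zero have a
conditional likelihood contribution of exactly one and are removed
during design assembly (their count is logged).

The linear predictor contains, besides the stratum intercepts:
unconstrained distributed-lag exposure indicators for lags 0–7 (no
smoothness constraint across lags), a linear lag-0 temperature term
(optionally lags 0–7, or none, as sensitivity variants), six
day-of-week indicators with Sunday as the (arbitrary, strata-absorbed)
reference, a natural cubic spline in integer calendar year with two
degrees of freedom for long-term trends, and a log-population offset
converting counts to rates. With binary exposure and lag-0 temperature
this is 8 + 1 + 6 + 2 = 17 covariate columns. The three-category
variant splits the lag block into gale- to violent-storm-force
(34–64 kt) and hurricane-force (≥ 64 kt) blocks with unexposed as
reference.

The spline basis is the truncated-power natural cubic construction
with boundary knots at the data extremes and internal knots at equally
spaced quantiles (df = 2 → one knot at the median year). Any basis
spanning the same space yields the same fit; this one is chosen for
reproducibility and testability (piecewise-cubic, curvature-continuous,
linear beyond the boundary — each property is asserted numerically).

Estimation profiles the stratum intercepts out of the Poisson
likelihood in closed form, α̂_s(β) = log(Y_s₊ / Σ_{i∈s} e^{o_i + x_i'β}),
and maximizes the profiled likelihood by Newton iterations whose
Hessian is the within-stratum weighted-centered information
X_c' W X_c — the exact information of the profiled (equivalently,
conditional multinomial) likelihood. This is memory-linear in strata;
an explicit dummy-intercept GLM is retained only as a test oracle and
agrees coordinate-wise to below 10⁻⁶ on small instances (measured:
~10⁻⁹). Convergence is declared when the relative log-likelihood
change falls below 10⁻⁸ (max 50 iterations, step-halving on any
decrease); starting values β = 0 are safe because the strata absorb
all baseline levels. Columns constant within every stratum are
non-identifiable and dropped with a warning, as are exactly collinear
columns (pivoted-QR detection on the centered design).

Inference is quasi-likelihood: covariance φ·(X_c' W X_c)⁻¹ with
Pearson dispersion φ = Σ(y−μ̂)²/μ̂ divided by residual df
n − p − (number of strata used), counting profiled intercepts as spent
parameters. A deviance-based dispersion is available behind a flag;
Pearson is the default because it directly estimates the
variance-to-mean ratio the quasi-Poisson variance function posits.

Effect summaries transform log rate ratios to percentage changes
100·(exp β − 1); Wald intervals are formed on the log scale and
exponentiated. Multiplicity over D outcome causes is handled with the
plain Bonferroni level α = 0.05/D (D = 13 by default, z ≈ 2.8905),
which yields fixed-width adjusted intervals; a step-down Holm p-value
routine is provided separately for hypothesis flags, since Holm does
not produce single fixed-level intervals. The cumulative effect is
Σβ_l with variance 1'Σ1 over the lag-covariance block; the average
effect divides both the sum and its SE by the number of lags. Note the
average percentage change transforms (Σβ_l)/8 and is not the mean of
the per-lag percentages.

Attribution converts the cumulative rate ratio into expected decadal
excess hospitalizations per county:
weekly_rate_c × population_c × ((exp Σβ_l)^{n_c} − 1), with
weekly_rate_c the average May–October weekly hospitalizations per
enrollee, population_c the mean enrollee count over the study period
(the year used for "the corresponding population" is otherwise
underdetermined; the mean is the package's choice and is explicit in
the baseline table), and n_c ten times the county's average exposure
days per year (non-integer n_c is meaningful and a real-valued power
is used). The formula is applied per county and summed. CI bounds
substitute the cumulative effect's log-scale interval endpoints into
the same formula, which is valid because it is monotone in the log
rate ratio; no delta-method approximation over the county sum is
attempted, and baseline rates and exposure frequencies are treated as
observed constants. A per-lag decomposition applies the same formula
with β_l in place of Σβ_l.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with every feature switchable:

- **Baseline**: `baseline_rate` expected daily hospitalizations per
  10,000 enrollees (default 1.0, a Medicare-like cause-level rate);
  populations drawn once per county, uniform on 5,000–50,000 enrollees,
  constant across years by default (a per-year drift knob exists; the
  offset is per county-year either way).
- **Seasonality and weekday**: a winter-peaking log-scale sinusoid
  (amplitude 0.2) and Monday–Saturday log effects of +0.07..+0.10 /
  −0.02 against a Sunday reference, mimicking weekday-dominant
  admissions.
- **Temperature**: summer-peaking sinusoid (15 ± 10 °C) plus N(0, 3 °C)
  noise, entering the count mean at 0.005/°C — enough to create the
  confounding structure the model adjusts for, without autocorrelation.
- **Exposure**: independent Bernoulli per county-day within
  May–October, calibrated to 0.18 expected exposure days per
  county-year (≈ 2.9 days per county over 16 years, matching the
  observed frequency of US tropical-cyclone wind exposure), 5% of
  exposure days at hurricane force; wind speeds drawn uniformly within
  the matching Beaufort band so classification round-trips exactly. A
  geometric run-length knob (default off) adds consecutive-day storm
  clustering for robustness experiments.
- **Counts**: NB1 (gamma-mixed Poisson, shape μ/(φ−1), scale φ−1),
  giving E = μ and Var = φμ — the variance law quasi-Poisson assumes.
  NB2 would make the effective φ mean-dependent and is deliberately not
  used. Default φ = 1.5, a modeling choice for mild overdispersion (the
  real-data dispersion is not publicly reported); φ = 1 is pure
  Poisson.
- **Reproducibility**: one integer seed; independent sub-streams for
  population, temperature, exposure, category, counts, and winds are
  spawned deterministically, so panels are bit-identical across runs.

What the generator does *not* emulate: spatial correlation between
counties, storm-track geometry (winds are drawn, not modeled from
tracks), temperature autocorrelation, population aging/migration
structure, and cause-specific coding behavior. Passing tests therefore
demonstrate correctness of the estimator and pipeline under the
assumed data-generating law, not robustness to the full messiness of
claims data.

## Problem sizes and numerical choices

Monte-Carlo validation uses 50 replicates of 100 counties × 8 years
(~292,000 rows, ~36,600 strata per replicate), true lag effects
(−0.05, 0.20, 0.10, 0.05, 0, 0, 0, 0) and φ = 1.5; mean bias of each
β̂_l stays within 3 Monte-Carlo SEs of zero and empirical 95% CI
coverage within [0.88, 1.00]. Dispersion recovery uses 10⁵ draws.
Oracle-equivalence checks use 20 random instances of ≤ 50 strata.
These sizes keep a full validation run at desk scale (a few minutes on
one CPU) while leaving Monte-Carlo error well below the tested margins.

Edge conventions: lags reaching before the panel start are treated as
unexposed rather than dropping the first week (exposures are rare, so
the bias is negligible); duplicate county-day wind records resolve to
the maximum wind; thresholds are inclusive at 34 and 64 kt with no
rounding before comparison; a units flag converts m/s-stored winds at
1 kt = 0.514444 m/s before thresholding. The Pearson dispersion floors
at machine epsilon so a degenerate exact fit keeps a positive, flagged
value. Zero standard errors yield degenerate, flagged intervals.

## Known limitations

- The conditional likelihood ignores between-stratum information by
  design; causes with very sparse counts may leave many strata dropped
  and estimates unstable (the dropped-stratum count is logged).
- Endpoint-substituted attribution intervals inherit only the
  cumulative effect's uncertainty; baseline rates and exposure
  frequencies contribute none.
- No penalized or constrained distributed-lag variants, no
  random-effects or spatial extensions, and no wind-field modeling from
  storm tracks — county-day winds (or categories) are consumed as
  inputs.
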