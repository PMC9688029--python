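# Methods

This note documents the models the package implements, the synthetic-data
generator that stands in for confidential survey/landings/trip data, and the
numerical and design choices that were genuinely open.

## Growth: ELEFAN with a genetic algorithm

### Model

Mean length at age follows the von Bertalanffy growth function in its t0-free
form, `L(t) = L∞ (1 − e^(−k t))`, where `L∞` (cm) is the asymptotic length and
`k` (year⁻¹) the rate at which it is approached. Because this form alone
cannot align cohorts with calendar sampling dates, the fitted parameter vector
is `(L∞, k, t_anchor)` with `t_anchor ∈ [0, 1)` the fraction of the calendar
year at which each annual cohort is born. `t_anchor` replaces the usual t0 and
has the same role as the anchoring parameter in the ELEFAN software lineage.

### Restructuring

Each monthly column of the length-frequency table (default 5 cm bins,
left-closed `[lower, lower + width)`) is converted to peak/trough scores by
the moving-average procedure: score = count / (centred moving average over
`ma` bins) − 1, with `ma = 5` by default. Cells whose moving average is zero
are defined as 0 (an all-zero month restructures to all zeros rather than
NaN). Isolated peaks are deflated by halving a positive score once per
zero-count immediate neighbour, and positive scores are then rescaled so they
sum to the magnitude of the negative scores within the column. The moving
average uses truncated windows at the grid edges. ASP (available sum of
peaks) is the grand sum of positive scores.

### Scoring and search

A candidate `(L∞, k, t_anchor)` implies one growth curve per annual cohort.
At every sampling date each cohort occupies exactly one length bin; the
explained sum of peaks (ESP) accumulates the scores of all (bin, month) cells
crossed by any cohort curve, each cell counted at most once, troughs included
with their negative sign. The goodness score is `Rn = 10^(ESP/ASP) / 10`,
in (0, 1], invariant to rescaling all counts by a positive constant.

The search is a small generational genetic algorithm: population 50,
100 generations, tournament selection (size 3), blend crossover, Gaussian
mutation with a per-parameter scale of 10% of the box width decaying 5-fold
over the run, elitism 2. Fitness ties are broken toward smaller `L∞` for
determinism. The default search box is `L∞ ∈ [0.8·Lmax, 1.3·Lmax]` (Lmax =
largest non-empty bin midpoint), `k ∈ [0.01, 1]`, `t_anchor ∈ [0, 1)`. All
settings are overridable; every run is a pure function of the seed.

### Uncertainty

Confidence intervals come from resampling the counts within each month
(multinomial with the month's total) and refitting; 0.95 percentile intervals
are reported for `L∞`, `k` and `Φ′ = 2 log₁₀ L∞ + log₁₀ k`. The conventional
production setting is 1000 resamples; tests use far fewer since they check
machinery, not precision.

### Identifiability — an honest limitation

Length data constrain `k·L∞` (the early growth rate) much better than either
parameter separately; the Rn surface has a long ridge with a spurious local
mode at low `L∞`/high `k`. Surface mapping with this package's generator shows
that for a *heavily exploited* stock (Z ≈ 0.47 with k = 0.12) the spurious
mode systematically outscores the truth: exponential survival leaves
essentially no near-asymptotic fish, the sparse upper tail restructures to
all-trough scores, and any curve that honestly traverses it is penalized while
a short curve stops below it. This reproduces the known tendency of ELEFAN-type
estimators to underestimate `L∞` and overestimate `k` for long-lived,
heavily fished stocks. The parameter-recovery experiments in the test suite
and acceptance script therefore simulate a lightly exploited population
(Z = 0.2), where the near-asymptotic pile-up makes `L∞` identifiable; growth
estimates from length data of heavily exploited long-lived stocks should be
treated with corresponding caution.

## Mortality

**Catch curve.** Counts pooled over months are converted bin-by-bin to
relative ages via the inverse growth curve `t(L) = −ln(1 − L/L∞)/k`; each
bin contributes `ln(N/Δt)` at the age of its midpoint, where `Δt` is the time
a cohort needs to grow through the bin. Ordinary least squares over the
descending limb gives `Z = −slope`, with the slope's standard error reported.
The default limb runs from the bin after the maximum of `ln(N/Δt)` through
the last non-empty bin with midpoint < 0.9·L∞ — the upper cutoff avoids the
region where `Δt` (and hence the age assignment) explodes as `L → L∞`. The
limb can be overridden, and zero-count bins inside a manual limb are dropped
with a warning. At least 3 regression points are required.

**Natural mortality.** Fourteen empirical estimators are evaluated from
`(L∞, k, tmax, T)` and averaged arithmetically; `tmax` defaults to the
longevity rule `3/k` carried at full precision, `T` to 18 °C. Two estimators
follow the exact algebraic form in which this battery is tabulated in the
applied literature rather than the textbook originals, because only those
forms reproduce the tabulated values: Alverson–Carney as
`3k / exp(0.38·tmax·k − 1)` and Pauly's temperature rule as
`exp(−0.0066 − 0.279 log₁₀L∞ + 0.6543 log₁₀k + 0.4634 log₁₀T)` (an `exp` of a
base-10-log expression). With `L∞ = 171.62`, `k = 0.13`, `tmax = 3/k`,
`T = 18` the battery reproduces the tabulated column (0.22, 0.13, 0.13, 0.34,
0.53, 0.13, 0.20, 0.21, 0.23, 0.21, 0.20, 0.18, 0.18, 0.18) and its mean 0.22
to two decimals; the tabulated values are internally consistent with
k ≈ 0.13, not the headline k = 0.12, and the package reproduces the stated
formulas rather than tuning inputs per row.

**Derived rates.** `F = Z − M` is returned together with an implausibility
flag when `M > Z` (negative F is reported, never clipped);
`E = F/(F + M) ∈ [0, 1)` maps `F = M` to exactly 0.5. Mean M is rounded only
at presentation; full precision propagates into F and E.

## Hurdle spatial distribution model

Station catch rates (rpn, individuals per 10³ hooks) are mostly zeros, so two
parts are fitted: binomial with logit link on presence/absence of all
stations, and Gaussian on `log(rpn)` of the positive stations (zero stations
contribute nothing to the second part — the defining hurdle property). Both
share the additive structure
`s(longitude, latitude) + s(depth) + substrate`:

* `s(longitude, latitude)`: a low-rank thin-plate radial smooth — the two
  standardized coordinates plus `r² log r` basis functions on a 4×4 quantile
  grid of knots, penalized by the radial energy matrix (projected to positive
  semi-definite), linear part unpenalized.
* `s(depth)`: a penalized cubic B-spline with basis dimension 4 by default.
* `substrate`: a treatment-coded factor over the seven seabed classes
  (C.Sed, Mix.Sed, Mud, Mud.S, Rock, Sand, Sand.M), reference C.Sed. A
  single-level factor is dropped with a warning.

Fitting uses penalized IRLS (statsmodels' GAM machinery). The smoothing
parameters default to a fixed mild penalty (α = 1 per smooth) for determinism
and speed; `select_penalty=True` switches to GCV-based selection on a
log-spaced grid. REML selection is not available in the underlying machinery,
which is why the fixed-penalty default was chosen over a stated-but-
unavailable criterion. Reported per part: deviance explained
`1 − D/D₀` (null deviance from the intercept-only model), Wald tests per
smooth term with effective degrees of freedom, coefficient tables for the
parametric terms, and for the Gaussian part an adjusted R² computed with
`n − edf` residual degrees of freedom. Perfect separation in the binomial part
is reported as a flag, not a crash.

Prediction returns presence probability, conditional abundance
(`exp` back-transform of the Gaussian prediction, no lognormal bias
correction by default) and optionally their product. Covariates outside the
training ranges are flagged as extrapolated and clipped to the training hull
for basis evaluation; an unseen substrate level is an error.

## Size structure and sex ratio

The Kolmogorov–Smirnov statistic is `D = sup|ECDF_x − ECDF_y|` with the
asymptotic p-value by default (sample sizes in this domain are in the
thousands); an exact mode is available for small samples. Welch's
heteroscedastic one-way F with Satterthwaite-type denominator df and
Games–Howell pairwise comparisons (studentized-range p-values with Welch df)
are computed via pingouin; zero-variance or n < 2 groups are rejected with a
message. Games–Howell confidence intervals use the 0.95 studentized-range
quantile. Sex-ratio tests are chi-square goodness of fit against 1:1 with
df = 1; the ratio is reported as males per female, an all-male stratum yields
an infinite ratio with the test still computed, and strata with n < 10 are
flagged "low n" rather than suppressed.

## Abundance standardization and trend comparison

The hurdle–lognormal GLM treats year, quarter, vessel class and gear/métier
as categorical factors (an optional continuous target fraction is binned to
quartile categories). Part 1 is a binomial GLM on `catch > 0` over all trips;
part 2 a Gaussian OLS on `log(catch/effort)` of positive trips. The annual
index is the least-squares mean of the year effect — the linear predictor
evaluated with every other factor averaged at equal level weights — combined
across parts as `exp(LSM_pos) · logit⁻¹(LSM_bin)` (a configuration flag
reports the positive part alone). Standard errors follow from the delta
method on the log scale: `Var(log index) ≈ Var(LSM_pos) + (1 − p)²·Var(LSM_bin)`.
When every trip is positive the binomial part is skipped (p = 1). A year with
no positive trips gets an undefined (NaN) index and a warning. On a balanced
noiseless design the standardized index equals the injected year multipliers
up to one global scale — this is checked exactly in the tests. LPUE and CPUE
differ only in the effort column supplied (landings events vs days at sea);
the code treats both identically.

Min–max normalization maps each index onto [0, 1] by `(x − min)/(max − min)`;
a constant series maps to 0.5 with a warning so degenerate simulations do not
abort pipelines.

Trend comparison stacks the normalized series and fits
`value ~ year * index`. The interaction F is computed directly as the
full-vs-pooled-slopes comparison, `F = (ΔSSR/(g−1)) / (SSR_full/df_res)` — 
algebraically the standard ANCOVA interaction test, but with explicit
handling of the zero-residual constructions used in validation: when the full
model fits perfectly, an interaction sum of squares at numerical zero gives
F = 0, p = 1, otherwise F = ∞, p = 0. If the interaction is not significant
at α = 0.05 the additive model is refit and all pairwise index contrasts are
tested with the Tukey adjustment (studentized-range distribution on
`|t|·√2` with the additive model's residual df); with zero residual variance
a nonzero offset is reported as p = 0 and a zero offset as p = 1. Tukey
contrasts are only run when slopes are parallel, mirroring the sequential
test-then-compare-intercepts logic of standard practice.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses assume.

**Population** (`PopulationParams`): annual recruitment pulses (default
4500 recruits, pulse in March, 30-year horizon); individual asymptotic length
lognormal with mean 170 cm and CV 7% (`k = 0.12` shared, so individual curves
never cross); death ages exponential with rate Z (default 0.47, the fished
stock), giving survival `exp(−Z·t)` and — because individuals persist across
sampling dates — coherent monthly cohort progression; sex Bernoulli with 68.5%
females (M:F = 0.46:1); logistic gear selectivity (default l50 = 40 cm,
slope 0.25 cm⁻¹ — the commercial fleet's selectivity is unknown, so these are
free parameters, not calibrated to any fishery). Lengths are binned
left-closed into 5 cm classes labelled by lower edge.

**Survey field** (`SpatialFieldParams`): presence logit =
`logit(1 − zero_inflation) + A·(g(depth) − 1) + substrate effect` with `g` a
Gaussian bump (optimum 300 m, scale 80 m, amplitude A = 4 logit units), so
zero_inflation (default 0.5) is the zero fraction at the optimum on the
reference substrate and overall zeros are ≈ 85–90% at uniform station depths,
matching the zero-heavy character of longline survey data. Positive rates are
lognormal (log-scale SD 0.6) around the same depth/substrate surface; the
default substrate effect is +1 log unit for Sand only.

**Fleet** (`FleetParams`): trip catch = base (100 kg) × year × quarter ×
vessel × gear multipliers × lognormal noise (SD 0.5), zeroed with probability
0.2. A `balanced=True` mode lays trips on the full factorial for closed-form
checks, and `vessel_trend` tilts the vessel-class mix across years to inject
a catchability confounder while true abundance stays flat.

**What the generator does not emulate:** spatial movement and autocorrelation
beyond the depth/substrate surface, environmental covariates, size-dependent
or senescent mortality, continuous recruitment, sex-specific growth, and any
calibration of fleet behaviour to a real fishery. Passing recovery tests on
these data therefore demonstrate correctness of the estimators under their
own assumptions, not robustness to the full messiness of real survey and
logbook data.

## Problem sizes in the shipped experiments

The test suite and acceptance script size their simulations to be decisive
but desk-scale: growth recovery on ~135 000 sampled fish over 24 months;
catch-curve recovery on a ~300 000-fish population pooled over 12 months;
SDM recovery and null calibration at 2000 stations; standardization at 480
balanced and 5000 confounded trips; Welch type-I calibration over 1000 null
datasets. The full suite runs in well under a minute apart from the GA fits,
which take a few seconds each.
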