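# lenstock

Length-based stock assessment for data-limited demersal fisheries, built
around the workflow used for deep-water species such as the silver
scabbardfish: no reliable age readings, no analytical assessment — only
length-frequency samples, survey station records and commercial trip records.

The package provides, as a tested Python library with a thin CLI:

* **Growth from length frequencies** — ELEFAN (electronic length-frequency
  analysis): monthly 5 cm length-frequency tables are restructured into
  peak/trough scores, and a genetic algorithm searches the von Bertalanffy
  parameters maximizing the goodness score `Rn = 10^(ESP/ASP) / 10`. The
  growth model is the t0-free form `L(t) = L∞ (1 − e^(−k t))` with a
  `t_anchor` parameter placing each annual cohort's birth within the calendar
  year. Bootstrap resampling of the monthly counts gives 95% percentile
  intervals; the growth performance index `Φ′ = 2 log₁₀ L∞ + log₁₀ k` is
  reported for cross-study comparison.
* **Mortality** — total mortality `Z` from the linearized length-converted
  catch curve (OLS of `ln(N/Δt)` on relative age over the descending limb);
  natural mortality `M` as the arithmetic mean of fourteen empirical
  estimators (longevity rules of the Beverton–Holt/Hoenig family with
  `tmax = 3/k`, temperature-based Pauly, and k-proportional rules of Jensen
  and kin); fishing mortality `F = Z − M` and exploitation rate
  `E = F/(F + M)`, with `E ≈ 0.5` the conventional optimal-exploitation
  benchmark.
* **Spatial distribution** — a two-part (hurdle) additive model for
  zero-inflated survey catch rates: binomial presence/absence and Gaussian
  log-abundance of positives, each with a bivariate thin-plate smooth of
  longitude/latitude, a penalized spline of depth and a seven-level substrate
  factor; deviance explained and term significance per part.
* **Size structure and sex ratio** — two-sample Kolmogorov–Smirnov tests,
  Welch's heteroscedastic one-way F with Games–Howell post hoc, chi-square
  goodness-of-fit tests of observed male:female counts against 1:1.
* **Abundance trends** — hurdle–lognormal GLM standardization of trip-level
  CPUE/LPUE (annual index = least-squares mean of the year effect, other
  factors balanced), min–max normalization onto [0, 1], and ANCOVA comparison
  of linear trends across indices with Tukey contrasts on intercepts when
  slopes are parallel.
* **Synthetic data** — seeded generators for all three data streams:
  cohort-structured populations growing by individual von Bertalanffy curves
  and dying at a constant total mortality rate, depth-peaked zero-inflated
  survey fields with substrate effects, and trip records with injected
  year/quarter/vessel/gear multipliers. Every analysis is testable without
  any confidential data.

## Worked example

Growth is estimated from 24 monthly samples of a lightly exploited synthetic
stock (true `L∞ = 170`, `k = 0.12`); the mortality chain runs on the fished
stock (true `Z = 0.47`) with known growth parameters:

```python
import pandas as pd
import lenstock as ls
from lenstock.growth import VBGFParams

dates = pd.period_range("2016-01", periods=24, freq="M")

lfq = ls.simulate_lfq(ls.PopulationParams(z=0.2, recruits_per_pulse=1800),
                      dates, seed=1)
fit = ls.fit_growth_ga(lfq, seed=1)
print(f"L-inf = {fit.point.linf:.1f} cm   k = {fit.point.k:.3f} per yr   "
      f"phi-prime = {fit.phi_prime:.2f}   Rn = {fit.rn_score:.3f}")

lfq_fished = ls.simulate_lfq(ls.PopulationParams(), dates, seed=1)
est = ls.mortality_estimates(lfq_fished, VBGFParams(170.0, 0.12))
print(f"Z = {est.z:.2f} +- {est.z_se:.3f} per yr   M = {est.m:.2f}   "
      f"F = {est.f:.2f}   E = {est.e:.2f}")
```

prints

```
L-inf = 155.2 cm   k = 0.139 per yr   phi-prime = 3.52   Rn = 0.523
Z = 0.48 +- 0.009 per yr   M = 0.20   F = 0.28   E = 0.57
```

The growth fit lands within 9% of the true `L∞` and 16% of the true `k`
(length data constrain the two jointly, along a ridge where `k·L∞` is nearly
constant, so `Φ′` is estimated much more precisely than either parameter).
The catch curve recovers the generator's `Z = 0.47` almost exactly; `M` here
is the fourteen-estimator mean evaluated at the growth parameters, and
`E > 0.5` flags a stock fished beyond the conventional optimum.

## Command line

```sh
lenstock simulate --out-dir data --seed 1          # synthetic lfq/survey/trips/fish CSVs
lenstock growth --lfq data/lfq.csv --bootstrap 200 --seed 1
lenstock mortality --lfq data/lfq.csv --linf 170 --k 0.12
lenstock sdm --survey data/survey.csv --depth-k 4
lenstock standardize --trips data/trips.csv
lenstock run --config config.yaml --out-dir out    # full pipeline
```

All CSV dialects are documented in `lenstock/io.py` (snake_case columns:
`date, length_lower, count` for length frequencies; station/position/depth/
substrate/rpn for surveys; year/quarter/vessel/gear/catch/effort for trips).

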