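# Methods

## Exposure metrics

Four exposure metrics share one analysis pipeline: PM2.5 (μg/m³), 8-hour
ozone (ppb), and two composites of the pair. The EPA AQI maps a
concentration to a 0–500 index by linear interpolation inside published
breakpoint intervals; following EPA reporting conventions, PM2.5 is
truncated (floored) to 0.1 μg/m³ and ozone to 1 ppb before the lookup, and
the interpolated index is rounded half-up. These conventions are the only
ones consistent with all four anchor pairs used in the tests
(4.9 μg/m³ → 20, 10.3 μg/m³ → 43, 36.9 ppb → 33, 54.9 ppb → 50). Breakpoints
ship as a CSV resource through the "very unhealthy" category (index 300);
higher concentrations raise an error rather than guessing an 8-hour-ozone
hazardous mapping. The *threshold* AQI is the maximum of the two
pollutant-specific indices (the regulatory definition); the *summed* AQI
adds them, treating joint exposure as cumulative. Agreement between the two
composite indices is measured with Kendall's tau-b — the tie-corrected
variant, because integerized indices are heavily tied.

Ozone is treated as ppb throughout: the 0–54 / 55–70 / 71–85 "good /
moderate / unhealthy-for-sensitive-groups" ranges are EPA's ppb breakpoints,
so source material quoting them in "ppm" is read as a units typo.

## Exposure histories

Each athlete-race observation gets an L-day exposure history (L = 21 by
default; 14 and 28 supported for sensitivity runs): lag 0 from the race
location on race day, lags 1..L−1 from the home-university location, the
assumption being that training happens at home and competition may be away.
Any missing (location, date) pair aborts the build with the offending keys
listed; nothing is imputed. Percentile contrasts (default 20th vs 80th) pool
all matrix entries and use numpy's linear-interpolation quantile rule; the
degenerate equal-percentile contrast is allowed and yields an exactly-zero
effect.

## Crossbasis

The natural cubic spline basis is built from the truncated-power
representation (N_1 = x, N_{m+1} = d_m − d_{K−2} with
d_m(x) = [(x−ξ_m)₊³ − (x−ξ_{K−1})₊³]/(ξ_{K−1}−ξ_m)), which spans natural
cubic splines — C², cubic between knots, linear beyond the boundary knots —
minus the constant. Cubic columns are rescaled by the squared boundary range
to keep them on the order of the linear column.

Dimension conventions:

* **Exposure dimension**: no intercept (its level is absorbed by the model
  intercept; all reported effects are two-point contrasts, so no centering
  value is stored). df columns ⇒ df − 1 internal knots. Boundary knots are
  the observed exposure range, stored in metadata so predictions are exactly
  reproducible.
* **Lag dimension**: one intercept column, counted in df (df 5 = constant +
  4 spline columns ⇒ 3 internal knots). Without the intercept every
  representable lag curve would be pinned to zero at lag 0 — the lag where
  acute exposure effects are expected to be largest — which measurably
  biases cumulative estimates; with it, the basis matches standard DLNM
  crossbasis construction.

Knot placement: when a spec is resolved against data, "equal" places
internal knots at equally spaced *quantile* positions of the observed
values. For the uniform lag grid this is numerically identical to equal
spacing on the value range (df 5 over lags 0–20 puts knots at 4, 8, 12, 16);
for a right-skewed exposure distribution it keeps every knot interval
populated, where value-range knots can leave the upper intervals nearly
empty and the corresponding crossbasis columns near-collinear.
"Logarithmic" placement spaces knots equally on log(t + 1) (defined at
lag 0), concentrating resolution at recent lags. A spec constructed with an
explicit boundary and no data uses equal value spacing.

Degenerate single-column bases (`kind="linear"`, `kind="const"`) collapse
the crossbasis to the L-day moving sum of exposure; they serve as
closed-form oracles in the tests (cumulative effect = L·b·Δx with SE equal
to a directly parameterized moving-sum regression).

## Mixed model

The marginal model is y ~ N(Xb, σ²I + σ²_race Z_rZ_r′ + σ²_uni Z_uZ_u′)
with crossed (non-nested) race and university intercepts. Estimation is
full ML, not REML, so AIC comparisons across fixed-effect sets are valid;
the AIC parameter count is p fixed coefficients + 2 variance components +
the residual variance. The likelihood is profiled over b and σ², leaving a
two-dimensional optimization over log variance ratios, evaluated through
the Woodbury identity on the q × q matrix Z′Z + D⁻¹ (q = number of groups).
After precomputing Z′Z, Z′X, Z′y, X′X, X′y, each evaluation costs
O(q³ + q²p) with no n-dependence, which is what makes 500-iteration
negative-control sweeps and 200-cohort recovery studies cheap. Optimization
uses bounded Nelder-Mead from three starts; a maximum-iteration stop on the
flat ridge where a variance ratio shrinks toward zero is accepted as a
usable optimum (the profile deviance is flat in that direction), and only a
total failure to produce a finite objective raises a convergence error.
Fixed-coefficient covariance is the profiled-ML expression
σ̂²(X′W⁻¹X)⁻¹, conditional on the estimated ratios. Correctness is
anchored by two independent oracles in the tests: direct evaluation of the
joint multivariate-normal density with the explicit n × n covariance, and
statsmodels MixedLM with crossed variance components.

Backwards-stepwise AIC deletes, at each step, the single covariate term
whose removal most decreases AIC (categorical terms leave as a block),
stopping when no deletion helps; it runs on the base model without
crossbasis terms, and the selected set is reused for every exposure metric.
Note the implied selection behaviour: a covariate with a true zero
coefficient is dropped only when its likelihood-ratio statistic is below 2,
an event with probability ≈ P(χ²₁ < 2) ≈ 0.84, so even pure-noise covariates
survive about one run in six — the tests assert the theoretically correct
rate rather than certain removal. Crossbasis-form selection refits the full
model over a (df 3/4/5 × equal/log) × (df 3/4/5 × equal/log) grid and
returns the AIC minimizer with the full table; ties break toward smaller
total df, then equal placement.

## Effect estimation

For a contrast vector v (difference of exposure-basis rows times summed
lag-basis rows), the estimate is v′β with delta-method SE √(v′Σv) and
1.96·SE confidence limits (normal approximation; no df correction, no
multiplicity adjustment across metrics). Per-lag estimates sum exactly to
the cumulative estimate. Contrasts outside the basis boundary trigger a
warning and use the natural linear extension. The delta-method SE is
cross-checked in the tests against the SD of 100,000 Monte-Carlo draws of
v′β*, β* ~ N(β̂, Σ).

## Negative exposure controls

Each iteration permutes whole exposure histories across observations
(preserving within-history autocorrelation while breaking the link to
outcomes), rebuilds the crossbasis, refits the model warm-started from the
unperturbed fit's variance ratios, and records whether the cumulative
20th-vs-80th effect's CI excludes zero. A resampling-with-replacement
variant is available behind a flag; the percentile contrast is recomputed
per perturbed matrix, which matters only for that variant. Reports are
bit-identical under a fixed seed; the permutation invariant (the multiset
of rows is preserved) is asserted every iteration.

## Synthetic cohort generator

The generator emulates the structure of a men's collegiate outdoor track
season: 46 universities × 7 athletes, 143 races hosted at university
locations between March 1 and June 30, and 1 + Poisson(2.4) race starts per
athlete, giving ≈ 1,100 athlete-race rows at full scale (a `desk_scale`
preset with 17 universities / 52 races yields ≈ 400 rows while keeping the
observation : race : university : athlete proportions). A 28-day lead-in of
daily pollution precedes the season so every history is complete.

Pollution is calibrated analytically, once, to the study's pooled
percentiles. PM2.5 is lognormal: pooled log-mean 1.9605 and pooled log-sd
0.4415 give 20th/80th percentiles exp(1.9605 ∓ 0.8416·0.4415) =
4.9 / 10.3 μg/m³ exactly; the log-variance splits into a between-location
sd of 0.30 and a within-location AR(1) with stationary sd 0.324 and lag-1
correlation 0.6. Ozone is Gaussian on the raw scale (truncated at 0):
pooled mean 45.9 and sd 10.695 ppb give 36.9 / 54.9, split as
between-location sd 6.0 and AR(1) stationary sd 8.85, correlation 0.6.

Covariates follow the cohort summary moments: personal record
N(844.5, 26.3²) s; previous time = personal record + |N(9, 9²)| (carrying
*no* signal about the outcome, so covariate selection has a genuine
zero-coefficient candidate); days since previous race N(20.4, 11²) for a
season opener and the actual date gap afterwards; school-year frequencies
101/257/355/391 out of 1,104; race-level temperature N(16.8, 7.1²) °C,
specific humidity N(8.7, 3.8²) g/kg (the summary table's "kg/kg" label is a
units slip — those numbers are g/kg), and wind drawn as a speed
N(3.7, 1.8²) m/s at a uniform random angle, stored as components.

The outcome adds, to an intercept set so the cohort mean is 857.3 s: linear
covariate effects (personal record 0.75 s/s, temperature 0.4 s/°C, humidity
0.3, wind 0.5, days-since −0.1, day-of-year −0.05, school-year offsets
0/−2/−4/−6), the exposure term Σ_l w_l·g(x_{i,l}), race and university
intercepts with sd 8 and 5 s, and residual noise with sd 12 s. The default
truth surface is linear, g(x) = 2.37·x, with geometric lag weights
w_l ∝ 0.8^l normalized to sum to one — so the cumulative 20th→80th PM2.5
contrast is 2.37·Δx ≈ 12.8 s, and the exposure response lies inside the
crossbasis span, making recovery a clean correctness check. A threshold
surface (outside the span) exists for robustness experiments only.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: spatial correlation of pollution between
universities, weather–pollution dependence, exposure measurement error from
downscaler extrapolation, athlete-level heterogeneity beyond the personal
record (no athlete random effect, matching the model), pacing/competition
dynamics, and altitude adjustment (times are generated already adjusted).

## Problem sizes and numerical choices

The recovery study uses 200 desk-scale cohorts (~400 observations each) and
the negative-control calibration 500 iterations on one desk-scale cohort —
sizes at which the full suite runs in a few minutes on one core while
leaving the binomial bands meaningful. Measured at these conditions:
95% CI coverage of the injected cumulative contrast 0.93 with 1.2% relative
bias of the mean estimate, and a negative-control significance fraction of
0.062 against the nominal 0.05.

Tolerances and tie-breaks: AQI index rounding is half-up with a 1e-9 guard
against inexact decimal floats; truncation uses the same guard. Rank
deficiency is detected on column-normalized QR pivots (relative tolerance
1e-10) and reported with the offending column names. Stepwise deletion ties
break alphabetically; crossbasis-form AIC ties break toward smaller total
df, then equal placement. Variance ratios are bounded in log space at
[−20, 12]. Natural-spline linearity beyond the boundary is exact by
construction; basis reproducibility from serialized metadata is exact.

## Known limitations

* The full-data reproduction of the published cumulative effects requires
  the original cohort (public, but not distributable here); the
  corresponding test documents the expected local layout and fails until
  the data is supplied.
* ML variance components are slightly biased downward at modest group
  counts (the price of AIC-valid comparisons); delta-method CIs ignore
  variance-parameter uncertainty. Both effects are visible only as
  coverage a point or two below nominal at desk scale.
* AQI composites are defined for PM2.5 + ozone only, and only up to index
  300 per pollutant.
* The negative-control permutation scheme is one reading of "perturbed
  exposure matrix"; the resampling variant is provided, and neither is
  claimed to be the original study's exact scheme.
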