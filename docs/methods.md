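# Methods

## Scope and data flow

The package estimates, per site and year, the water requirement (WR),
irrigation water requirement (IWR) and water suitability (S) of apple
during three phenophases — flowering–fruit setting, fruit expansion,
coloring–maturity — from daily weather alone. The chain is: flowering
date (model ensemble) → phenophase windows → daily crop-coefficient
curve → daily FAO-56 Penman–Monteith ET₀ → stage water balance.

## Phenology models

All four models are driven by the daily mean temperature
T = (Tmax + Tmin)/2; the sources of these model families do not fix the
daily statistic, and the mean is the customary choice. Rates accumulate
from a start day; flowering is the first day the running sum meets the
requirement, and a season that never meets it yields an explicit
"no prediction".

* **M1 (photothermal time)**: Σ (L_i/24)^k · max(T_i − T_b, 0) ≥ F\*,
  with L_i the astronomical daylength. The daylength weight is applied
  per-day on the rate (the standard photothermal-time form; moving the
  scaling across the inequality makes it algebraically equivalent to a
  right-hand-side scaling). k = 0 recovers plain growing degree days.
* **Uniforc**: sigmoidal forcing 1/(1 + exp(b(T − c))), b < 0.
* **Alternating**: degree-day forcing above a threshold; the requirement
  a + b·exp(c·CD) relaxes with the chill-day count CD (days below the
  same threshold). Chill days are counted from September 1 of the
  preceding year, the conventional start of the dormancy season, and
  include the current day.
* **Unichill**: chilling accumulates from t0 (a day offset from
  September 1) with the bell response 1/(1 + exp(a_c·dT² + b_c·dT)),
  dT = T − c_c, until C\* is reached on day t_c; sigmoidal forcing then
  accumulates from the following day until F\*. C\* = 0 degenerates to
  Uniforc started at t0. A flowering day that would fall before
  January 1 of the target year is treated as no prediction.

Continuous start parameters (t1, t0) map to the first whole day ≥ t1.
The batch predictor stacks seasons into a padded matrix (122 lead days
from September 1 plus up to 366 target-year days) and is the single
numerical code path; per-series functions wrap a one-row batch. The
logistic is saturated beyond |x| = 500 to avoid overflow.

### Ensemble

Member predictions are averaged with normalised inverse-RMSE weights
w_m = (1/RMSE_m)/Σ(1/RMSE_k) from validation, and rounded half away from
zero (flowering dates are calendar days). Members without a prediction
are dropped and the remaining weights renormalised; the reading of the
weight formula as normalised inverse RMSE is the only one that sums to
one and down-weights worse models. A model with zero validation error
would receive all the weight (shared among ties).

## Calibration

Each model is fitted by minimising the calibration RMSE with
scipy's basin-hopping over parameters standardised to their bound ranges
(each scaled to [0, 1]); the hop step of 0.5 and the iteration count are
tunable (the classical configuration is 1000 iterations). The local
search is a bounded Nelder–Mead simplex: the objective is piecewise
constant in the integer flowering day, so gradient methods are
inappropriate, and in our experiments Powell stalls in the flat region
where no parameter vector flowers. The hop chain starts from the best of
a seeded uniform presample (default 256 draws), which reliably lands the
first local search in a flowering-capable region. A season with no
prediction enters the objective as day 465 (365 plus a 100-day penalty),
steering the optimiser away from degenerate corners. Observations are
sorted internally, so the objective is invariant to input order. The
70/30 calibration/validation split is random by default, optionally
stratified by site.

Default bounds: t1, t0 ∈ [1, 150]; thresholds and sigmoid midpoints
∈ [−5, 20] °C; F\* ∈ (0, 200]; C\* ∈ (0, 150]; sigmoid slopes ∈ [−5, 0);
a_c ∈ (0, 2]; b_c ∈ [−2, 2]; k ∈ [0, 2]; Alternating a ∈ [0, 300],
b ∈ [0, 1000], c ∈ [−0.1, 0].

The calibration hot loop evaluates the season matrix in single
precision (~2× faster); the public prediction API is double precision.
The rounding difference is far below the day-level granularity of the
objective.

## Phenophase windows and Kc curve

Fruit set falls `d1` days after flowering (April 3 flowering with a
30-day stage puts fruit set on May 3); fruit expansion spans the
following `d2` days and coloring–maturity the `d3` after that, each
stage inclusive of both endpoints and abutting the next. Defaults
(22, 102, 39) days are configurable per region; a season that would
overrun the calendar year is rejected rather than truncated.

Kc anchors: 0.33 during dormancy, a linear green-up reaching 0.45 the
day before flowering (default 60-day ramp), a jump to 0.75 at flowering
onset, a linear rise to the 0.95 plateau by fruit set, and 0.95 held
through fruit expansion. Through coloring–maturity the default holds
0.95; a `late_decline` option ramps linearly to a configurable
`k_late_end` instead — monitoring descriptions support both readings.
After maturity the curve relaxes linearly back to 0.33 over 30 days.

## Reference evapotranspiration

Daily FAO-56 Penman–Monteith with G = 0 at the daily step and
R_n = R_ns − R_nl. Two formula corrections are applied by default, each
with a `strict_printed` audit mode reproducing the uncorrected variant:

* Δ is computed from e(Tmean); the variant using the actual vapour
  pressure e_a would make the slope humidity-dependent, contradicting
  its definition and the saturation-curve formula it derives from.
* Net longwave uses √e_a in the emissivity term (the constant
  2.45 × 10⁻⁹ = σ/2 together with the sum of the two fourth powers
  identifies the standard form).

Wind measured at height z_h (default 10.5 m) is brought to 2 m with the
logarithmic profile u₂ = u_h·4.87/ln(67.8 z_h − 5.42), which gives the
published 0.743 factor at 10.5 m. Solar declination defaults to the
cosine approximation −0.4093·cos(2πJ/365); the FAO sine form is a
configuration switch (differences < 0.02 rad, < 2 % in R_a — note the
cosine form places the equinoxes near DOY 91/274). Kelvin conversions
use 273 exactly as in the source formulas. A negative numerator (cold
overcast days) floors ET₀ at zero with a diagnostic flag.

## Water balance

WR_j = Σ Kc(i)·ET₀(i) over the stage. Effective precipitation uses the
USDA-SCS piecewise formula applied **daily** and summed per stage: the
8.2 mm breakpoint is clearly sub-monthly and the stage windows are
daily, so the classical monthly application would be inconsistent here.
The two pieces disagree by ≈ 0.015 mm at the breakpoint; this is treated
as a known bounded discontinuity. IWR_j = WR_j − P_eff,j when positive,
else zero; S_j = P_eff,j/WR_j; six classification bands, half-open
below, from "Worst suitability" (S < 0.4) to "Excessive moisture"
(S ≥ 2.0). WR = 0 cannot occur with physically positive ET₀ but is
guarded.

## Synthetic data

The generator emulates mid-latitude (27–44 °N) orchard climate:

* temperature: sinusoidal annual cycle with its minimum at mid-January,
  configurable mean (default 12 °C) and half-amplitude (14 °C), i.i.d.
  Gaussian daily noise (2.5 °C), fixed diurnal range (10 °C);
* precipitation: two-state Markov occurrence (lag-1 persistence 0.3)
  whose day-varying target probability carries a monsoonal cycle —
  wettest in mid-July with amplitude 0.6 around an annual-mean wet-day
  probability of 0.25 — with exponential wet-day amounts (mean 6 mm):
  the simplest generator producing realistic wet/dry runs and the
  dry-spring / wet-summer contrast of the study region for the
  piecewise daily effective precipitation;
* humidity and wind: clipped Gaussians (RH 60 ± 12 %, wind mean 2.5 m/s
  at 10.5 m); sunshine: a noisy fraction (0.6 ± 0.15) of the
  astronomical daylength.

Site climates cool with latitude (−0.55 °C/deg north of 35°) and
elevation (−0.6 °C/100 m) and gain seasonality northward. Flowering
observations are model predictions plus rounded Gaussian noise
(site-years that never flower are dropped with a warning). Generating
truths were chosen once, from forward simulation, to give realistic
spring flowering (~DOY 90–180 across the belt). For the sigmoid forcing
model the truth uses a moderately steep response (slope −0.5, midpoint
6 °C) whose rate saturates during spring, which keeps the forcing
requirement well identified. For the sequential model the truth is
forcing-dominated: its chilling requirement completes in mid-winter at
every site, consistent with apple's chilling demand being comfortably
met across most of this temperate belt; the consequences for
identifiability are discussed under limitations.

Not emulated: spatial correlation between sites, autocorrelated
temperature noise, humidity–precipitation coupling, trends. The default
climate is drier than the humid parts of the real production belt, so
absolute suitability values sit lower than real-region reporting even
though the dry-spring/wet-summer contrast is present. Passing tests
therefore demonstrate correctness of the algorithms and the
recoverability of parameters under the stated noise model, not
performance on real station data.

## Experiment sizes and numerical choices

The packaged experiments use 6 sites × 27 years (≈ 150 usable
site-years), observation noise 2 d, and reduced basin-hopping budgets
(80–200 hops, local simplex capped at 200–300 evaluations, presample
256–512); recovery statistics are reported as medians over 10 seeds,
since single fits wander the likelihood ridge even when the validation
RMSE matches the injected noise. Equal-width summary histograms default
to 20 mm (WR/IWR) and 0.2 (S), right-open.

## Known limitations

* **Chilling-requirement identifiability.** For the sequential
  chilling–forcing model, flowering dates alone do not constrain C\*.
  Whenever chilling completes before forcing becomes effective — the
  usual situation for apple in this belt — any (t0, C\*, bell) triple
  with an early enough completion day fits identically. And even under
  a deliberately chilling-limited truth, a near-flat bell (a_c → 0)
  makes every day contribute ≈ 0.5 chilling units, so t_c ≈ t0 + 2C\*
  and the triple still trades off freely: deep optimisation reaches
  validation RMSE at the injected noise level with C\* anywhere from
  roughly half to twice the truth. Recovering C\* to better than tens of
  percent would need independent chilling observations or narrow
  informative bounds on the bell parameters. The recovery experiment
  reports this honestly rather than constraining the fit toward the
  truth; its C\*-recovery check documents the failure instead of hiding
  it.
* Forcing-requirement recovery for the sigmoid model is ridge-limited
  too (F\* trades off against the sigmoid midpoint and slope); medians
  over seeds recover to a few percent under the saturating default
  truth, while single seeds can deviate by ~20–50 %.
* The ET₀ module follows the daily FAO-56 parameterisation; hourly
  dynamics, measured radiation inputs and crop-height generalisations
  are out of scope.
* Suitability classification uses the six printed band labels; regional
  prose synonyms ("unsuitable", "fairly/relatively suitable",
  "very/extremely suitable") map onto these bands but are not emitted.
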