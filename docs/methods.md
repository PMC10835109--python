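# Methods

## Problem and model

`aqadapt` quantifies the costs and benefits of *avoidance adaptation* to
outdoor fine particulate matter (PM2.5): staying indoors on polluted days in
response to air-quality alerts, under a reference climate scenario and a
mitigated counterpart with cleaner outdoor air.

The causal chain, per grid cell and year of 365 daily 24-h mean
concentrations:

1. **Alerts.** The EPA Air Quality Index maps a 24-h mean PM2.5
   concentration onto a 0–500 index by piecewise-linear interpolation between
   published breakpoints (2012-vintage table embedded, swappable).
   Concentrations are truncated to 0.1 µg/m³ and the index rounded to the
   nearest integer before comparison, following EPA convention; an alert day
   is a day whose integer AQI *strictly* exceeds the threshold (100 for
   sensitive groups = 35.4 µg/m³, 150 for the general population =
   55.4 µg/m³). ADY is alert days per year; EADY is the change versus the
   start-of-century epoch, with replicate-mean pairing.

2. **Exposure.** A person normally spends `Tout` hours/day outdoors; indoors,
   a fraction `FINF` of outdoor PM2.5 is present. Adapting (staying in all
   24 h) scales that day's contribution to annual exposure by

       psi = 24·FINF / (Tout + (24 − Tout)·FINF),

   which lies in [FINF, 1]. The post-adaptation *equivalent annual mean* over
   an adaptation-day set A is `( Σ_{n∉A} PM_n + psi·Σ_{d∈A} PM_d ) / 365`.
   The single-day formula generalizes additively to arbitrary day sets
   because the chain is linear in concentration; a day's marginal benefit
   against the no-adaptation baseline therefore equals its contribution in
   any set.

3. **Health and money.** The drop in equivalent annual mean ΔPM lowers
   all-cause mortality via the linearized concentration–response form

       ΔI = Y0 · (RR − 1)/RR · ΔPM / 10 µg/m³,

   with relative risk RR = 1.14 per 10 µg/m³ and cell baseline mortality Y0.
   The printed attributable-fraction form is used as-is (not exponentiated);
   a BenMAP-style log-linear alternative `1 − exp(−ln(RR)/10 · ΔPM)` is
   available behind `cr_form="loglinear"` (the two differ by ~7% at
   RR = 1.14). Benefits are monetized at the value of a statistical life,
   VSL = $7.9 million (2008 USD) × 1.27 CPI inflation to 2020 USD ≈ $10.0 M.
   The cost of adapting a day is the outdoor time given up, `phi·xi·Tout`,
   with `phi` defaulting to the cell's mean hourly wage and `xi` (fraction of
   outdoor time given up) = 1 for Threshold/Rational/Forced.

## Decision strategies

* **Threshold** — compliers adapt exactly on alert days (AQI > 100 or
  > 150); compliance defaults to 20%, the current share of Americans who
  restrict outdoor time in response to poor air quality. Population-weighted
  values scale linearly with compliance.
* **Rational actor** — adapts on every day with non-negative marginal net
  benefit. Implemented as a greedy scan in decreasing-concentration order
  (ties broken by day index — selection within a tie is NB-invariant) that
  stops at the first negative day. Linearity makes this set optimal over all
  2^365 subsets and identical to the closed-form threshold set
  {days with PM > PM\*}, where

      PM* = C_d·365·10·RR / (VSL·Y0·(RR−1)·(1−psi)).

* **Forced** — adds days in decreasing-concentration order, regardless of
  sign, until the equivalent annual mean reaches the mitigated scenario's
  annual mean (integer day counts; slight overshoot allowed). When even a
  full indoor year cannot reach the target — leaky housing with psi near 1 —
  the outcome is returned flagged infeasible rather than raising. Benefits
  and costs accrue for every selected day, so net benefits can be deeply
  negative.
* **Social learning** — replicator dynamics on the adopter share x of each
  cell, advanced quarterly to track seasonal pollution:
  `x' = clip(x + kappa_r·sigma_i·x(1−x)·ΔU, 0, 1)` with
  `ΔU = (R − C)/R0 + delta_r·(2·omega(x) − 1)`. Adopters comply with that
  quarter's alerts. Perceived risk R defaults to the quarter's summed
  single-day health benefits over alert days (perceived = objective) with a
  configurable misperception multiplier; C is the quarter's summed cost with
  the region's fitted `xi_r`. `omega(x) = x` by default (a smoothed-step
  alternative is provided). Cell population `sigma_i` is normalized to mean
  1 across cells so `kappa_r` is scale-free; denser cells still move
  proportionally faster. Annual outcomes weight each quarter's alerts by the
  adopter share in force during that quarter.

### Fitting the social-learning model

`fit_social_learning` recovers (kappa_r, delta_r, xi_r) per census region
from quarterly adoption trajectories by multi-start bounded least squares
(scipy `least_squares`, trust-region reflective; 8 seeded starts, one
deterministic mid-range start), simulating forward from the observed initial
share. R0 is held fixed during fitting: kappa multiplies and R0 divides the
same utility term, so the pair is not jointly identifiable from trajectories
alone. Constant observed trajectories sit at a fixed point where any kappa
fits; these are returned flagged non-identifiable. Goodness of fit is
adjusted R² with p = 3 parameters. On noiseless self-generated data the fit
recovers parameters to well under 1% relative error; quarterly observation
noise of sd 0.02 degrades adjusted R² as expected.

## Aggregation and uncertainty

National summaries are population-weighted means over cells (weights: adult
population, ages 25–99). Subgroup cumulative distributions of ADY/EADY
weight each cell's contribution to a race/income/leakage group by that
group's population in the cell.

Health/valuation uncertainty is propagated by Monte Carlo (default 5,000
draws; 2,000 in the bundled pipeline): ln(RR) normal with a 95% interval of
(1.07, 1.22) truncated to RR > 1, VSL lognormal with arithmetic sd 0.6× the
mean — conventional stand-ins, config-swappable. Adaptation-day sets are
frozen at central-estimate parameters across draws, so the intervals reflect
statistical, not behavioral, uncertainty, and costs carry no interval.
Intervals are empirical 2.5/97.5 percentiles (the lognormal VSL skews the
benefit distribution, so normal approximations would be wrong). Because
benefits are linear in VSL and monotone in RR, interval endpoints scale
exactly with the VSL distribution. If the true (RR, VSL) are themselves
draws from the assumed distributions, the 95% interval covers the true
benefit at the nominal rate (verified at ±3 percentage points over 500
repetitions).

The mitigation benefit of a scenario row values the REF→mitigated drop in
the cell-population mean exposure *for that row's partially adapting
population* (compliers at the adapted equivalent mean). Adapters staying
indoors are less exposed to outdoor air, so adaptation shrinks the
mitigation benefit — the interaction the summary table reproduces.

## Synthetic study conditions

The generator's defaults define the study conditions; they are not tuned.

* **Daily concentrations**: seasonal sinusoid (winter peak, amplitude 0.4×
  the annual mean) times stationary lognormal AR(1) multiplicative noise
  (lag-1 log autocorrelation 0.6, coefficient of variation 0.4), clipped at
  0 and rescaled to hit the target annual mean exactly. This reproduces the
  right skew and day-to-day persistence of real PM2.5 without external data.
* **Annual-mean anchors**: start-of-century 12 µg/m³ (the era in which
  simulated national means matched EPA-reported averages); end-of-century
  reference 21.5 µg/m³. The latter is calibrated from two stated quantities:
  a 1.2 µg/m³ mitigation shift and the observation that fully offsetting it
  takes about 142 additional adaptation days per year at Tout = 1 h,
  FINF = 0.2 — inverting the equivalent-annual-mean formula for a constant
  series, 365·1.2/(c·(1−psi)) = 142 gives c ≈ 21.5. Cell means spread ±35%
  (uniform, fixed per cell) around the anchor; replicates differ only in
  noise realization.
* **Mitigation**: a 1.2 µg/m³ annual-mean reduction applied proportionally
  per day (preserving the daily pattern and non-negativity), not
  re-simulated chemistry.
* **Demographics**: wage lognormal (mean $27/h, sd $8); adult baseline
  mortality lognormal (mean 0.009/yr, sd 0.002); Tout = 1 h/day;
  infiltration 0.15 ± 0.03 in tighter and 0.35 ± 0.07 in leakier housing
  (half of cells each), straddling the 0.2 national default; income group
  assigned by wage against the configured median; a Gaussian copula with
  rank correlation −0.5 between the wage and leakage scores places leakier
  housing preferentially in lower-income cells; census regions sampled with
  US-like probabilities; race shares Dirichlet per region.

What the generator does **not** emulate: spatial correlation between
neighboring cells, wildfire episodes, indoor-source PM2.5, trends within an
epoch, demographic projection, and leap days (years are fixed at 365 days).
Passing tests therefore demonstrate internal consistency of the method and
its orderings under realistic marginal structure — not agreement with any
observed concentration field.

## Numerical choices and degenerate inputs

* AQI: concentration truncated to 0.1 µg/m³, index rounded to nearest
  integer; concentrations above the table maximum clamp to the top index
  with a warning; "exceeds threshold" is strict on the integer index.
* Rational tie-break by day index; equal-concentration boundary ties are
  NB-invariant (each tied day contributes NB = 0 at the break-even point).
* Forced stops at the first integer day count reaching the target;
  overshoot is bounded by one day's maximum increment (1−psi)·max(PM)/365.
* psi is undefined (0/0) at Tout = 0 with FINF = 0 and raises; FINF = 1
  gives psi = 1 and an infinite break-even concentration (adaptation cannot
  change exposure).
* A mitigation shift larger than the annual mean returns an all-zero series
  with a warning rather than negative concentrations.
* Monte-Carlo point-mass distributions yield zero-width intervals (valid).
* Scenario NetCDF I/O uses the NetCDF-3 classic format (xarray scipy
  backend) with float64 payloads; a long-format CSV fallback stores 9
  significant digits. Both validate day counts and non-negativity on read.
* Every random operation derives its seed from the master seed plus a stable
  component tag (CRC-32 of the tag into a `SeedSequence`), so identical
  configs give byte-identical outputs.

## Known limitations

* Net benefits are **not** monotone in Tout under wage-valued costs: the
  per-day cost phi·Tout grows linearly while the exposure benefit saturates
  (1−psi → 1−FINF), so population net benefits peak (near Tout ≈ 2 h at the
  default conditions) and then decline. The sweep tests assert monotonicity
  only in the low-Tout regime where health benefits dominate; gross benefits
  are monotone in Tout unconditionally.
* The morbidity and ozone pathways, cessation lag, and age-stratified
  concentration–response are out of scope; benefits here are adult all-cause
  mortality only.
* Social-learning perceived risk anchored to objective benefits is one
  defensible choice among several; the misperception multiplier is the
  escape hatch, not a fitted quantity.
* Dollar magnitudes depend on the synthetic concentration and demographic
  surfaces and are not calibrated to any deposited dataset; orderings and
  interaction signs are the tested claims.
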