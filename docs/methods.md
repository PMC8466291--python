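# Methods

## Effective temperature

The thermal environment inside naturally ventilated calf housing is
summarised per hour by the wind-adjusted effective-temperature index

    ET = 37 − (37 − t) / [0.68 − 0.0014·ur + 1/(1.76 + 1.4·v^0.75)]
            − 0.29·t·(1 − ur/100)

with air temperature *t* (°C), relative humidity *ur* (%) and wind speed
*v* (m/s).  ET equals *t* at typical barn conditions, is strictly
increasing in *t*, non-increasing in *v* below 37 °C (wind amplifies
cold), and has a fixed point ET(37, 100, v) = 37 where both correction
terms vanish — these properties are enforced by tests.  The closed form
follows the Suping-type formulation used by R's ThermIndex `etv`
function; it was transcribed and verified against hand-evaluated oracle
points (frozen in the test suite) rather than against the R package
itself, and it sits behind a single pure function
(`climate.effective_temperature`) so an alternative index can be swapped
in without touching the exposure code.  The index deliberately ignores
radiant (solar) heat; the temperature–humidity index (THI) is not
offered because it omits wind, which matters in open-sided housing.

## Climate ingestion

Hourly stamps are timezone-naive local time and denote the start of the
hour.  Validation drops rows with unparseable timestamps, humidity
outside [0, 100] % or negative wind speed (collected in a JSON report);
identical duplicate rows are de-duplicated, conflicting duplicates are a
hard error.  Gaps of at most 3 h are forward-filled and flagged; longer
gaps — and the hours of rejected rows — are left absent and are excluded
from both the numerator and denominator of every exposure proportion, so
missingness does not bias the statistic.  Sensor heights are metadata
only.

## Lower critical temperature and exposure

Two LCT definitions are provided.  The physiological form

    T_lc = (T_r + H'_e,min · I_e) − H_min · (I_t + I_e)

(rectal temperature, external/tissue insulation, minimum evaporative
heat loss, thermoneutral heat production) is evaluated exactly but never
parameterised from data.  Routine exposure scoring uses the simplified
age schedule: 15 °C at birth (day 0) declining 0.5 °C per day of age, no
floor by default (a floor is configurable; over a ~32-day horizon the
schedule stays at or above −1 °C).

A calf's exposure over a phase is the proportion of available hours with
ET strictly *below* the age-related LCT (equality is not below).  Age
advances at 24-hour anniversaries of the birth timestamp — day
boundaries are calf-relative, not calendar midnights.  The hutch-phase
window runs from birth to hutch exit; the group-phase window from pen
entry to the last weighing.  Proportions are rounded half-up to two
decimals and banded into the study's four phase categories (B2G: ≤0.32,
0.33–0.58, 0.59–0.96, ≥0.97; G2E: ≤0.01, 0.02–0.06, 0.07–0.27, ≥0.28);
rounding first closes the gaps between the printed two-decimal
cut-points (e.g. 0.325 → 0.33).  The first band is always the modelling
reference level.

## Health status and eligibility

Wisconsin scores cover five aspects (rectal temperature, ocular and
nasal discharge, head/ear posture, cough), each 0–3, summed to 0–15;
faecal consistency is not scored (group-housed calves cannot be matched
to faeces).  Status: Healthy if rectal ≤ 2 and overall ≤ 3; Intermediate
if rectal ≤ 2 and overall = 4; Diseased if rectal = 3 or overall ≥ 5 —
a total partition of all valid score pairs, tested exhaustively.  A calf
"ever showed signs of disease" if any phase record is non-Healthy.

Hutch-phase eligibility requires a recorded birth weight and a hutch-exit
age of at most 14 whole days (`floor((exit − birth)/24 h)`, matching
integer reported ages).  Group-phase eligibility further excludes calves
that died/were euthanised, were sold, returned to a hutch, lack a
complete daily milk record (a record for every calendar day from pen
entry to last weighing — losses in the source setting were whole blocks
from power failures), or have fewer than two group-pen weights.  When a
calf fails several rules, only the first in that order is logged, so
per-reason counts are disjoint and sum with the eligible count to the
roster size.

## Growth and intake

B2G DLWG is the interval rate (exit weight − birth weight)/whole days.
G2E DLWG is the OLS slope of weight on age in days over repeated
weighings (at least two weighings with distinct ages; on exactly two
points the slope equals the interval rate — an identity under test).
The slope is invariant to using age or days-since-entry as regressor.
Average CMR (calf milk replacer) intake is total recorded powder mass
divided by the phase day count; reconstitution is weight-per-volume, so
volume (L/d) × concentration (%) × 10 gives g/d (6 L/d at 15% = 900 g/d).

## The modelling chain

Each phase's candidate covariates are screened univariably against DLWG;
terms with whole-term p < 0.20 enter a maximal model, reduced by
backward elimination: at each step the term with the largest whole-term
p ≥ 0.05 is dropped (ties broken by dropping the term later in the
candidate order), until all remaining terms are significant.  Whole-term
tests are partial F-tests for the OLS (B2G) path and maximum-likelihood
likelihood-ratio tests for the mixed (G2E) path, because multi-level
factors need a single joint test; per-level Wald p-values against the
reference level are reported alongside.  The G2E model carries three
*crossed* random intercepts — rearing group, igloo pen, milk-feeder
system — fitted by REML via statsmodels `MixedLM` variance components;
crossed rather than nested is the weaker structural assumption and the
grouping columns are configurable.  Random intercepts are structural and
never candidates for elimination; a random term observed at a single
level is dropped with a warning, and an unestimable mixed fit falls back
to a fixed-effects fit with a warning.  Perfectly collinear terms are
detected by an incremental rank check on the design matrix; the
later-listed term is dropped deterministically.

Numerical choices: MixedLM is optimised with Powell's method (Nelder–Mead
fallback).  The gradient-based optimisers in statsmodels stall when a
variance component's optimum lies on the zero boundary — common here,
with only two feeder systems and eight pens — whereas the derivative-free
search reaches the boundary cleanly; at estimated zero variance the
mixed fit reproduces OLS coefficients to ~1e-10, and Powell and
Nelder–Mead agree to < 1e-4 kg/d (both tested).  Singular (zero-variance)
fits are legitimate results, not errors.

Tukey post-hoc contrasts among a retained factor's levels use the
Tukey–Kramer studentised-range adjustment on model-adjusted level
effects and their covariance: p = Q_sf(|δ|/se(δ)·√2; k, ν) with ν the
residual degrees of freedom (for mixed models, n minus fixed-effect
count — a conventional approximation).  On a balanced one-way design
this reproduces `statsmodels.stats.multicomp.pairwise_tukeyhsd`, and for
a two-level factor the adjusted p equals the unadjusted t-test p.  No
multiplicity correction is applied across screening, matching the
source procedure.

## Synthetic-data generator

The generator emulates the study conditions, not any particular real
dataset:

* **Climate** — annual sinusoid (amplitude 6 °C, coldest mid-January)
  plus diurnal sinusoid (amplitude 2 °C, warmest 15:00) plus Gaussian
  noise (SD 2.65 °C) around 10.3 °C; the variance budget a²/2 + d²/2 + σ²
  reproduces the target marginal SD 5.2 °C over a year.  Humidity is
  normal (81.1, 11.3²) clipped to [27, 99] %; wind is zero with
  probability 0.7, otherwise exponential (scale 0.667 m/s) capped at
  3 m/s, giving mean ≈ 0.2 and a zero median.
* **Cohort** — birth weights truncated-normal 43.2 ± 6.2 kg on [31, 67];
  hutch-exit ages 6–14 d with the study's frequency profile; sex, breed,
  parity and calving ease drawn independently at the study's marginal
  proportions (the joint distribution is not published); births uniform
  over the year.
* **Growth** — each calf's exposure category is *computed through the
  same climate → ET → LCT → proportion chain the pipeline uses*, never
  drawn independently; recovery of the growth coefficients is therefore
  an end-to-end test of the whole chain.  B2G DLWG is drawn from the
  published hutch-phase linear predictor (intercept 0.537; category
  effects 0/−0.061/−0.157/−0.199; birth weight −0.018; exit age +0.028)
  with residual SD 0.30 kg/d — chosen below the marginal SD 0.34 because
  part of that spread is explained by the covariates.  G2E growth slopes
  come from the group-phase predictor (entry age +0.009, CMR +0.001 per
  g/d, near-null category effects) plus random intercepts for group, pen
  and feeder (SD 0.05 kg/d each; not reported, stated default) and
  residual SD 0.15 kg/d.  The published group-phase coefficients include
  no intercept; the default −0.373 kg/d makes the implied mean DLWG at mean
  covariates equal the observed phase mean 0.60 kg/d.
* **Measurements** — weighings twice weekly (alternating 3/4-day steps)
  to an end age of 29.5 ± 1.2 d (truncated [25, 32]), with 0.5 kg
  measurement noise on repeat weighings (an invented, documented knob);
  the per-calf OLS slope therefore carries the estimation error a real
  study would see.  Daily CMR intakes are truncated-normal
  890.5 ± 152.3 g/d on [489.8, 1223.7] plus daily noise; the *realised*
  phase average is used in the linear predictor, so coefficient recovery
  has no errors-in-variables attenuation by construction.  Health scores
  and treatments are generated as no-effect nuisance covariates.
* **Exclusions** — an optional plan marks designated calves ineligible
  for exactly one printed reason each (1 missing birth weight, 27
  over-age, 5 died, 1 sold, 3 returned, 41 incomplete milk), so the
  filters reproduce the 299 → 271 → 221 arithmetic.

All randomness flows from one seed through named substreams (appended,
never reordered), making every artefact byte-reproducible.  What the
generator does **not** emulate: spatial structure within the barn,
serial correlation in health, weather beyond first/second moments and
the two cycles, seasonal breeding patterns, or informative missingness —
so passing recovery tests demonstrates correctness of the computation
chain under the stated model, not robustness to real-data pathologies.

## Recovery study and problem sizes

`calftherm.recovery` regenerates 200 replicates per phase (n = 271 for
the hutch phase, 221 for the group phase — the study's analysis sizes),
refits the known-truth models and averages the estimates; the acceptance
script reports those replicate means.  Two hundred replicates put the
Monte-Carlo standard error of each mean at roughly 1/14 of a single
replicate's standard error (e.g. ≈ 0.012 kg/d for the hutch-phase
intercept), which resolves the generating values at their printed
precision while keeping the full run to a few minutes on one CPU.

## Known limitations

* Mixed-model degrees of freedom for Tukey contrasts use the residual
  approximation rather than Satterthwaite/Kenward–Roger.
* LRT p-values for mixed-model fixed effects are asymptotic; with eight
  pens and two feeder systems the variance components themselves are
  weakly identified (their point estimates frequently sit at zero).
* The exposure statistic weights all hours equally; no radiant-heat or
  wind-chill-behaviour (huddling, nesting) adjustment is attempted.
* `filter_g2e` checks milk completeness on calendar days, which assumes
  feeder logs are dated daily summaries.
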