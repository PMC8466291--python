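# calftherm

Does a cold housing environment slow the growth of pre-weaned dairy
calves?  `calftherm` implements the full analysis chain for answering
that question from routinely collected farm records: hourly barn climate,
calf rosters, repeated weighings, Wisconsin health scores and automatic
milk-feeder logs.

It is written for veterinary epidemiologists and animal-science
researchers studying naturally ventilated calf housing, where air
temperature alone understates cold exposure and where the threshold that
matters — the calf's **lower critical temperature** (LCT) — falls as the
calf ages.

## The model

Hourly climate records (air temperature *t* °C, relative humidity *ur* %,
wind speed *v* m/s) are combined into a wind-adjusted **effective
temperature**

```
ET = 37 − (37 − t) / [0.68 − 0.0014·ur + 1/(1.76 + 1.4·v^0.75)]
        − 0.29·t·(1 − ur/100)
```

Each calf's LCT follows an age schedule (15 °C at birth, −0.5 °C per day;
the physiological form `T_lc = (T_r + H'_e,min·I_e) − H_min·(I_t + I_e)`
is also provided).  The exposure statistic per housing phase is the
proportion of available hours with `ET < LCT(age)`, banded into four
phase-specific categories.  Growth is daily liveweight gain (DLWG, kg/d):
an interval rate for the individual-hutch phase (birth to group entry,
"B2G"), and a least-squares weight-on-age slope for the group-pen phase
(group entry to study end, "G2E").

The statistical chain mirrors standard observational-study practice:
univariable screening at p < 0.20, a maximal multivariable model reduced
by backward elimination to p < 0.05 (ordinary least squares for B2G; a
linear mixed model with crossed random intercepts for rearing group, pen
and milk-feeder system for G2E), and Tukey–Kramer post-hoc contrasts
among the levels of retained factors.

Because such farm datasets are rarely public, the package ships a
synthetic-study generator calibrated to a year-long Scottish cohort
(299 calves, birth weights 43.2 ± 6.2 kg, barn air temperature
10.3 ± 5.2 °C, …) whose growth responses are drawn from published fitted
models — so the entire chain can be exercised, and its parameter
recovery verified, end to end.

## Worked example

```bash
calftherm simulate --outdir study --seed 2     # synthetic study (CSV files)
calftherm b2g --study-dir study --outdir out   # hutch-phase analysis
```

prints

```
DLWG linear model  (n = 271)
response: dlwg
screening (alpha = 0.2): kept prop_cat, birth_weight, exit_age, season
dropped 'season' (p = 0.522)
    variable        level  estimate    se  p_reference  p_effect
   Intercept                  0.239 0.156
    prop_cat <=0.32 (ref)                                  0.000
    prop_cat    0.33-0.58    -0.113 0.052        0.032
    prop_cat    0.59-0.96    -0.228 0.042        0.000
    prop_cat       >=0.97    -0.180 0.057        0.002
birth_weight                 -0.011 0.003                  0.000
    exit_age                  0.028 0.008                  0.001
residual variance: 0.0807
```

Reading it: of 299 generated calves, 271 were eligible (recorded birth
weight, hutch exit at ≤ 14 days).  Calves spending ≥ 97% of their hutch
hours below their age-related LCT grew about 0.18 kg/d slower than
calves below it ≤ 32% of the time; heavier-born calves grew slightly
slower (−0.011 kg/d per kg) and calves that stayed longer in the hutch
slightly faster (+0.028 kg/d per day).  Season screened in but was
eliminated — its apparent effect is explained by the exposure category.
`out/` holds the analysis table, exclusion log, model table, selection
trace and Tukey contrasts; `calftherm g2e` runs the group-phase mixed
model and `calftherm report` writes descriptive summary tables.

The same objects are available as a library:

```python
from calftherm import DlwgModel, simulate_b2g_dataset

df = simulate_b2g_dataset(seed=2)
res = DlwgModel.from_dataframe(
    df, response="dlwg",
    candidate_terms=["prop_cat", "birth_weight", "exit_age"]).fit()
print(res.summary());  res.tukey("prop_cat")
```

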