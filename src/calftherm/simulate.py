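"""Synthetic study generator: barn climate and calf cohorts.

The generator reproduces the statistical structure of a year-long,
single-farm longitudinal calf study so the whole analysis chain can be
exercised — and its parameter recovery verified — without external data.

Climate is an annual + diurnal sinusoid with Gaussian hourly noise,
calibrated so the marginal moments match the study barn (air temperature
mean 10.3 °C, SD 5.2; relative humidity mean 81.1 %, SD 11.3, clipped to
[27, 99]; wind speed mostly zero, mean 0.2 m/s, capped at 3).

Cohorts draw birth weights from a truncated normal (43.2 ± 6.2 kg on
[31, 67]), hutch-exit ages 6–14 d from the study's frequency profile, and
covariates from the study's marginal proportions.  Crucially, each calf's
cold-exposure category is **computed through the same climate → effective
temperature → LCT → proportion chain under test**, not drawn
independently; hutch-phase DLWG is then drawn from the fitted hutch-phase
linear predictor (intercept 0.537; category effects 0 / −0.061 / −0.157 /
−0.199; birth weight −0.018 per kg; exit age +0.028 per day) plus
residual noise, and group-phase growth slopes from the group-phase
predictor (entry age +0.009, CMR intake +0.001 per g/d) plus crossed
random intercepts for rearing group, pen and feeder system.

All randomness flows from one seed through named substreams
(:data:`STREAM_NAMES`), so adding a stream never reorders existing draws.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from calftherm.climate import hourly_et_series
from calftherm.cohort import season_of_birth
from calftherm.exposure import (
    B2G_SCHEME,
    G2E_SCHEME,
    AgeLCTSchedule,
    categorise_exposure,
)

__all__ = [
    "ClimateGenConfig",
    "CohortGenConfig",
    "ExclusionPlan",
    "generate_climate",
    "generate_cohort",
    "generate_study",
    "simulate_b2g_dataset",
    "simulate_g2e_dataset",
    "STREAM_NAMES",
]

#: substream order — append-only, never reorder
STREAM_NAMES = (
    "climate", "births", "covariates", "exit_age", "birth_weight",
    "b2g_resid", "grouping", "end_age", "cmr", "g2e_resid", "weight_noise",
    "health", "treatment", "exclusions",
)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
    return {name: np.random.default_rng(child)
            for name, child in zip(STREAM_NAMES, children)}


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


@dataclass(frozen=True)
class ClimateGenConfig:
    """Annual/diurnal sinusoid-plus-noise barn climate.

    The variance budget amplitude²/2 (annual) + amplitude²/2 (diurnal) +
    noise² reproduces the target marginal SD of air temperature over a
    full year.
    """

    start: str = "2019-01-01"
    n_days: int = 398  # one birth year plus the longest calf window (32 d)
    mean_level: float = 10.3
    annual_amplitude: float = 6.0
    coldest_day_of_year: int = 15
    diurnal_amplitude: float = 2.0
    warmest_hour: int = 15
    noise_sd: float = 2.65
    rh_mean: float = 81.1
    rh_sd: float = 11.3
    rh_clip: tuple[float, float] = (27.0, 99.0)
    wind_zero_prob: float = 0.7
    wind_scale: float = 0.667
    wind_max: float = 3.0

    def __post_init__(self):
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")
        if not 0 <= self.wind_zero_prob <= 1:
            raise ValueError("wind_zero_prob must lie in [0, 1]")
        if self.rh_clip[0] >= self.rh_clip[1]:
            raise ValueError("rh_clip bounds must be ordered")


@dataclass(frozen=True)
class GrowthCoefs:
    """Generating coefficients of one phase's DLWG linear predictor."""

    intercept: float
    category: tuple[float, float, float, float]
    slopes: dict = field(default_factory=dict)  # covariate -> coefficient


#: hutch-phase (B2G) fitted model used as generator truth
B2G_COEFS = GrowthCoefs(
    intercept=0.537,
    category=(0.0, -0.061, -0.157, -0.199),
    slopes={"birth_weight": -0.018, "exit_age": 0.028},
)

#: group-phase (G2E) fitted model used as generator truth.  The source
#: model table prints no intercept; −0.373 kg/d makes the implied mean
#: DLWG at mean covariates equal the observed phase mean of 0.60 kg/d.
G2E_COEFS = GrowthCoefs(
    intercept=-0.373,
    category=(0.0, -0.037, -0.008, 0.002),
    slopes={"entry_age": 0.009, "avg_cmr": 0.001},
)


@dataclass(frozen=True)
class ExclusionPlan:
    """How many calves to make ineligible, per printed exclusion reason."""

    missing_birthweight: int = 1
    overage: int = 27
    died: int = 5
    sold: int = 1
    returned: int = 3
    missing_milk: int = 41


@dataclass(frozen=True)
class CohortGenConfig:
    """Cohort-level generating distributions and effect structure."""

    n_calves: int = 271
    birth_start: str = "2019-01-01"
    birth_span_days: int = 365
    birth_weight_mean: float = 43.2
    birth_weight_sd: float = 6.2
    birth_weight_clip: tuple[float, float] = (31.0, 67.0)
    # hutch-exit-age counts for ages 6..14 d from the study cohort
    exit_age_weights: tuple = (19, 52, 45, 45, 29, 28, 27, 16, 10)
    female_prob: float = 171 / 299
    dairy_prob: float = 226 / 299
    primiparous_prob: float = 109 / 299
    assisted_prob: float = 36 / 299
    b2g_coefs: GrowthCoefs = B2G_COEFS
    b2g_resid_sd: float = 0.30
    g2e_coefs: GrowthCoefs = G2E_COEFS
    g2e_resid_sd: float = 0.15
    re_sd_group: float = 0.05
    re_sd_pen: float = 0.05
    re_sd_feeder: float = 0.05
    n_groups: int = 24
    n_pens: int = 8
    cmr_mean: float = 890.5
    cmr_sd: float = 152.3
    cmr_clip: tuple[float, float] = (489.8, 1223.7)
    cmr_daily_sd: float = 80.0
    end_age_mean: float = 29.5
    end_age_sd: float = 1.2
    end_age_clip: tuple[float, float] = (25.0, 32.0)
    weight_noise_sd: float = 0.5
    health_sick_prob: float = 0.11
    treat_b2g_prob: float = 37 / 271
    treat_g2e_prob: float = 95 / 221
    lct_schedule: AgeLCTSchedule = AgeLCTSchedule()

    def __post_init__(self):
        if self.n_calves <= 0:
            raise ValueError("n_calves must be positive")
        if any(w < 0 for w in self.exit_age_weights):
            raise ValueError("exit-age weights must be non-negative")
        for lo, hi in (self.birth_weight_clip, self.cmr_clip,
                       self.end_age_clip):
            if lo >= hi:
                raise ValueError("truncation bounds must be ordered")
        for sd in (self.b2g_resid_sd, self.g2e_resid_sd, self.re_sd_group,
                   self.re_sd_pen, self.re_sd_feeder, self.weight_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


def generate_climate(config: ClimateGenConfig | None = None,
                     seed: int = 0,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One hourly climate record per hour of the configured span."""
    config = config or ClimateGenConfig()
    rng = rng if rng is not None else _streams(seed)["climate"]
    n = config.n_days * 24
    ts = pd.date_range(config.start, periods=n, freq="h")
    doy = ts.dayofyear.to_numpy()
    hour = ts.hour.to_numpy()
    temp = (config.mean_level
            - config.annual_amplitude
            * np.cos(2 * np.pi * (doy - config.coldest_day_of_year) / 365.25)
            + config.diurnal_amplitude
            * np.cos(2 * np.pi * (hour - config.warmest_hour) / 24.0)
            + rng.normal(0.0, config.noise_sd, n))
    rh = np.clip(rng.normal(config.rh_mean, config.rh_sd, n), *config.rh_clip)
    calm = rng.random(n) < config.wind_zero_prob
    wind = np.where(calm, 0.0,
                    np.minimum(rng.exponential(config.wind_scale, n),
                               config.wind_max))
    return pd.DataFrame({"timestamp": ts, "air_temp": temp,
                         "rel_humidity": rh, "wind_speed": wind})


def _exposure_fast(et: np.ndarray, series_start: pd.Timestamp,
                   birth_hours: np.ndarray, start_hours: np.ndarray,
                   end_hours: np.ndarray,
                   schedule: AgeLCTSchedule) -> np.ndarray:
    """Vectorised per-calf proportion of hours with ET below age LCT.

    All times are whole-hour offsets from the first climate hour; window
    is [start, end).  Raises if any window runs off the climate series.
    """
    n_hours = len(et)
    if np.any(start_hours < 0) or np.any(end_hours > n_hours):
        raise ValueError("calf window not covered by the climate series")
    props = np.empty(len(birth_hours))
    for i, (b, s, e) in enumerate(zip(birth_hours, start_hours, end_hours)):
        hours = np.arange(s, e)
        age_days = (hours - b) // 24
        lct = schedule.lct_at_birth - schedule.daily_decline * age_days
        if schedule.floor is not None:
            lct = np.maximum(lct, schedule.floor)
        props[i] = np.mean(et[s:e] < lct)
    return props


def _assign_categories(props, scheme):
    labels = [categorise_exposure(p, scheme) for p in props]
    return pd.Categorical(labels, categories=list(scheme.labels))


def simulate_b2g_dataset(seed: int, n: int = 271,
                         climate_config: ClimateGenConfig | None = None,
                         config: CohortGenConfig | None = None
                         ) -> pd.DataFrame:
    """One hutch-phase analysis table generated end to end.

    Births are uniform over the configured year; each calf's exposure
    category is computed through the climate → ET → LCT chain; DLWG is
    drawn from the hutch-phase linear predictor with the configured
    residual SD.  Columns: ``dlwg``, ``prop_cat`` (ordered categorical),
    ``birth_weight``, ``exit_age``, ``prop_b2g``.
    """
    config = config or CohortGenConfig(n_calves=n)
    climate_config = climate_config or ClimateGenConfig()
    rngs = _streams(seed)
    climate = generate_climate(climate_config, rng=rngs["climate"])
    et = hourly_et_series(climate)["effective_temp"].to_numpy()
    t0 = pd.Timestamp(climate_config.start)

    birth_day = rngs["births"].integers(0, config.birth_span_days, n)
    birth_hour = rngs["births"].integers(0, 24, n)
    birth_hours = birth_day * 24 + birth_hour
    ages = np.arange(6, 6 + len(config.exit_age_weights))
    probs = np.asarray(config.exit_age_weights, dtype=float)
    probs /= probs.sum()
    exit_age = rngs["exit_age"].choice(ages, size=n, p=probs)
    birth_weight = _truncnorm(rngs["birth_weight"], config.birth_weight_mean,
                              config.birth_weight_sd,
                              *config.birth_weight_clip, n)

    props = _exposure_fast(et, t0, birth_hours, birth_hours,
                           birth_hours + exit_age * 24, config.lct_schedule)
    cats = _assign_categories(props, B2G_SCHEME)
    coefs = config.b2g_coefs
    cat_eff = np.asarray(coefs.category)[cats.codes]
    mu = (coefs.intercept + cat_eff
          + coefs.slopes["birth_weight"] * birth_weight
          + coefs.slopes["exit_age"] * exit_age)
    dlwg = mu + rngs["b2g_resid"].normal(0.0, config.b2g_resid_sd, n)
    return pd.DataFrame({"dlwg": dlwg, "prop_cat": cats,
                         "birth_weight": birth_weight,
                         "exit_age": exit_age.astype(float),
                         "prop_b2g": props})


def simulate_g2e_dataset(seed: int, n: int = 221,
                         climate_config: ClimateGenConfig | None = None,
                         config: CohortGenConfig | None = None
                         ) -> pd.DataFrame:
    """One group-phase analysis table generated end to end.

    The response is the calf's estimated weight-on-age slope: the true
    slope from the group-phase predictor plus group/pen/feeder random
    intercepts and residual, perturbed by the slope-estimation error
    implied by twice-weekly weighings with the configured measurement SD.
    """
    config = config or CohortGenConfig(n_calves=n)
    climate_config = climate_config or ClimateGenConfig()
    rngs = _streams(seed)
    climate = generate_climate(climate_config, rng=rngs["climate"])
    et = hourly_et_series(climate)["effective_temp"].to_numpy()
    t0 = pd.Timestamp(climate_config.start)

    birth_day = rngs["births"].integers(0, config.birth_span_days, n)
    birth_hour = rngs["births"].integers(0, 24, n)
    birth_hours = birth_day * 24 + birth_hour
    ages = np.arange(6, 6 + len(config.exit_age_weights))
    probs = np.asarray(config.exit_age_weights, dtype=float)
    probs /= probs.sum()
    entry_age = rngs["exit_age"].choice(ages, size=n, p=probs)
    end_age = np.round(_truncnorm(rngs["end_age"], config.end_age_mean,
                                  config.end_age_sd, *config.end_age_clip, n))

    props = _exposure_fast(et, t0, birth_hours,
                           birth_hours + entry_age * 24,
                           birth_hours + (end_age.astype(int)) * 24,
                           config.lct_schedule)
    cats = _assign_categories(props, G2E_SCHEME)

    order = np.argsort(birth_hours, kind="stable")
    group = np.empty(n, dtype=int)
    group[order] = np.arange(n) * config.n_groups // n
    pen = group % config.n_pens
    feeder = np.where(group < int(np.ceil(0.61 * config.n_groups)),
                      "HL100", "BioControl")

    avg_cmr = _truncnorm(rngs["cmr"], config.cmr_mean, config.cmr_sd,
                         *config.cmr_clip, n)
    rg = rngs["grouping"]
    u_group = rg.normal(0.0, config.re_sd_group, config.n_groups)[group]
    u_pen = rg.normal(0.0, config.re_sd_pen, config.n_pens)[pen]
    u_feeder = rg.normal(0.0, config.re_sd_feeder, 2)[
        (feeder == "BioControl").astype(int)]

    coefs = config.g2e_coefs
    cat_eff = np.asarray(coefs.category)[cats.codes]
    mu = (coefs.intercept + cat_eff
          + coefs.slopes["entry_age"] * entry_age
          + coefs.slopes["avg_cmr"] * avg_cmr)
    slope = mu + u_group + u_pen + u_feeder \
        + rngs["g2e_resid"].normal(0.0, config.g2e_resid_sd, n)

    # slope-estimation error of an OLS fit to twice-weekly weighings
    sxx = np.array([_weighing_sxx(a, e) for a, e in zip(entry_age, end_age)])
    slope_hat = slope + rngs["weight_noise"].normal(
        0.0, config.weight_noise_sd / np.sqrt(sxx))

    return pd.DataFrame({"dlwg": slope_hat, "prop_cat": cats,
                         "entry_age": entry_age.astype(float),
                         "avg_cmr": avg_cmr, "group_id": group,
                         "pen_id": pen, "feeder_system": feeder,
                         "prop_g2e": props})


def _weighing_ages(entry_age: int, end_age: float) -> np.ndarray:
    """Twice-weekly weighing schedule: entry, then +3/+4 d alternating."""
    ages = [int(entry_age)]
    step = 3
    while ages[-1] + step <= end_age:
        ages.append(ages[-1] + step)
        step = 7 - step
    return np.asarray(ages, dtype=float)


def _weighing_sxx(entry_age: int, end_age: float) -> float:
    ages = _weighing_ages(entry_age, end_age)
    return float(np.sum((ages - ages.mean()) ** 2))


def generate_cohort(config: CohortGenConfig | None = None,
                    climate: pd.DataFrame | None = None,
                    seed: int = 0,
                    exclusions: ExclusionPlan | None = None) -> dict:
    """Full longitudinal record bundle for one synthetic cohort.

    Returns a dict of DataFrames: ``roster``, ``weights``, ``health``,
    ``milk``, plus ``truth`` holding each calf's latent growth parameters
    (for recovery checks).  With an :class:`ExclusionPlan`, designated
    calves are made ineligible exactly one printed reason each, so the
    eligibility filters reproduce the study's exclusion arithmetic.
    """
    config = config or CohortGenConfig()
    climate_config = ClimateGenConfig()
    rngs = _streams(seed)
    if climate is None:
        climate = generate_climate(climate_config, rng=rngs["climate"])
    else:
        _ = rngs["climate"]  # keep substream order stable
    et_frame = hourly_et_series(climate)
    et = et_frame["effective_temp"].to_numpy()
    t0 = pd.Timestamp(climate["timestamp"].iloc[0])
    n = config.n_calves

    birth_day = rngs["births"].integers(0, config.birth_span_days, n)
    birth_hour = rngs["births"].integers(0, 24, n)
    birth_hours = np.sort(birth_day * 24 + birth_hour, kind="stable")
    births = t0 + pd.to_timedelta(birth_hours, unit="h")

    rc = rngs["covariates"]
    sex = np.where(rc.random(n) < config.female_prob, "female", "male")
    breed = np.where(rc.random(n) < config.dairy_prob, "dairy", "dairy-beef cross")
    parity = np.where(rc.random(n) < config.primiparous_prob,
                      "primiparous", "multiparous")
    ease = np.where(rc.random(n) < config.assisted_prob, "assisted", "unassisted")

    ages = np.arange(6, 6 + len(config.exit_age_weights))
    probs = np.asarray(config.exit_age_weights, dtype=float)
    probs /= probs.sum()
    exit_age = rngs["exit_age"].choice(ages, size=n, p=probs)
    birth_weight = _truncnorm(rngs["birth_weight"], config.birth_weight_mean,
                              config.birth_weight_sd,
                              *config.birth_weight_clip, n)

    # designate excluded calves up front, disjointly, before any windows
    rx = rngs["exclusions"]
    plan = exclusions
    missing_bw = np.zeros(n, bool)
    overage = np.zeros(n, bool)
    died = np.zeros(n, bool)
    sold = np.zeros(n, bool)
    returned = np.zeros(n, bool)
    milk_gap = np.zeros(n, bool)
    if plan is not None:
        total_excl = (plan.missing_birthweight + plan.overage + plan.died
                      + plan.sold + plan.returned + plan.missing_milk)
        if total_excl > n:
            raise ValueError("exclusion plan larger than the cohort")
        chosen = rx.choice(n, size=total_excl, replace=False)
        cursor = 0
        for count, mask in ((plan.missing_birthweight, missing_bw),
                            (plan.overage, overage), (plan.died, died),
                            (plan.sold, sold), (plan.returned, returned),
                            (plan.missing_milk, milk_gap)):
            mask[chosen[cursor:cursor + count]] = True
            cursor += count
        exit_age = exit_age.copy()
        exit_age[overage] = 15 + rx.integers(0, 2, int(overage.sum()))

    exit_hours = birth_hours + exit_age * 24
    props_b2g = _exposure_fast(et, t0, birth_hours, birth_hours, exit_hours,
                               config.lct_schedule)
    cats_b2g = _assign_categories(props_b2g, B2G_SCHEME)
    coefs = config.b2g_coefs
    mu_b2g = (coefs.intercept + np.asarray(coefs.category)[cats_b2g.codes]
              + coefs.slopes["birth_weight"] * birth_weight
              + coefs.slopes["exit_age"] * exit_age)
    dlwg_b2g = mu_b2g + rngs["b2g_resid"].normal(0.0, config.b2g_resid_sd, n)
    lh_weight = birth_weight + dlwg_b2g * exit_age

    group = np.arange(n) * config.n_groups // n  # birth-order batches
    pen = group % config.n_pens
    feeder = np.where(group < int(np.ceil(0.61 * config.n_groups)),
                      "HL100", "BioControl")
    rg = rngs["grouping"]
    u_group = rg.normal(0.0, config.re_sd_group, config.n_groups)[group]
    u_pen = rg.normal(0.0, config.re_sd_pen, config.n_pens)[pen]
    u_feeder = rg.normal(0.0, config.re_sd_feeder, 2)[
        (feeder == "BioControl").astype(int)]

    end_age = np.round(_truncnorm(rngs["end_age"], config.end_age_mean,
                                  config.end_age_sd, *config.end_age_clip, n))
    end_age = np.maximum(end_age, exit_age + 7)  # keep >= 2 weighings

    # daily CMR intakes; the realized phase average is the model covariate
    latent_cmr = _truncnorm(rngs["cmr"], config.cmr_mean, config.cmr_sd,
                            *config.cmr_clip, n)
    rcmr = rngs["cmr"]
    rres = rngs["g2e_resid"]
    rw = rngs["weight_noise"]
    rh_ = rngs["health"]
    rt = rngs["treatment"]

    weight_rows, milk_rows, health_rows = [], [], []
    avg_cmr = np.zeros(n)
    slope_true = np.zeros(n)
    calf_ids = [f"C{i + 1:03d}" for i in range(n)]
    g2e_props = np.full(n, np.nan)

    for i in range(n):
        cid = calf_ids[i]
        entry_dt = t0 + pd.Timedelta(hours=int(exit_hours[i]))
        w_ages = _weighing_ages(int(exit_age[i]), float(end_age[i]))
        if died[i]:
            w_ages = w_ages[:1]  # died early: entry weight only
        last_age = w_ages[-1]
        # daily milk from pen entry to last weighing (calendar days)
        birth_date = (t0 + pd.Timedelta(hours=int(birth_hours[i]))).normalize()
        entry_date = entry_dt.normalize()
        last_date = (t0 + pd.Timedelta(
            hours=int(birth_hours[i] + last_age * 24))).normalize()
        days = pd.date_range(entry_date, last_date, freq="D")
        daily = np.clip(latent_cmr[i]
                        + rcmr.normal(0.0, config.cmr_daily_sd, len(days)),
                        0.0, None)
        if milk_gap[i] and len(days) > 3:
            daily = daily.copy()
            keep = np.ones(len(days), bool)
            keep[len(days) // 2:len(days) // 2 + 3] = False  # power failure
            days, daily = days[keep], daily[keep]
        avg_cmr[i] = daily.sum() / max(len(pd.date_range(entry_date, last_date,
                                                         freq="D")), 1)
        for d, mass in zip(days, daily):
            milk_rows.append({"calf_id": cid, "date": d.date().isoformat(),
                              "milk_volume": round(mass / 150.0, 3),
                              "cmr_mass": round(mass, 1)})

        gco = config.g2e_coefs
        cat_idx = None  # category assigned after window known
        if len(w_ages) >= 2:
            p = _exposure_fast(et, t0, np.array([birth_hours[i]]),
                               np.array([birth_hours[i] + int(exit_age[i]) * 24]),
                               np.array([birth_hours[i] + int(last_age) * 24]),
                               config.lct_schedule)[0]
            g2e_props[i] = p
            cat_idx = list(G2E_SCHEME.labels).index(
                categorise_exposure(p, G2E_SCHEME))
        mu = (gco.intercept
              + (gco.category[cat_idx] if cat_idx is not None else 0.0)
              + gco.slopes["entry_age"] * exit_age[i]
              + gco.slopes["avg_cmr"] * avg_cmr[i])
        slope_true[i] = (mu + u_group[i] + u_pen[i] + u_feeder[i]
                         + rres.normal(0.0, config.g2e_resid_sd))

        for k, a in enumerate(w_ages):
            wt = lh_weight[i] + slope_true[i] * (a - exit_age[i])
            if k > 0:
                wt += rw.normal(0.0, config.weight_noise_sd)
            weight_rows.append({
                "calf_id": cid,
                "datetime": (t0 + pd.Timedelta(
                    hours=int(birth_hours[i] + a * 24))).isoformat(),
                "weight": round(float(wt), 1),
                "weighing_number": k + 1,
            })
            # health scored at each weighing
            if rh_.random() < config.health_sick_prob:
                overall = int(rh_.integers(4, 9))
                rectal = int(min(rh_.integers(0, 4), 3, overall))
                rest = overall - rectal
            else:
                overall = int(rh_.integers(0, 4))
                rectal = int(rh_.integers(0, min(overall, 2) + 1))
                rest = overall - rectal
            comp = np.zeros(4, dtype=int)
            for _ in range(rest):  # spread remainder over the 4 other aspects
                slot = int(rh_.integers(0, 4))
                if comp[slot] < 3:
                    comp[slot] += 1
            overall = rectal + int(comp.sum())
            health_rows.append({
                "calf_id": cid,
                "datetime": (t0 + pd.Timedelta(
                    hours=int(birth_hours[i] + a * 24))).isoformat(),
                "rectal_score": rectal, "ocular_score": int(comp[0]),
                "nasal_score": int(comp[1]), "ear_score": int(comp[2]),
                "cough_score": int(comp[3]), "overall_score": overall,
            })

    roster = pd.DataFrame({
        "calf_id": calf_ids,
        "birth_datetime": [b.isoformat() for b in births],
        "sex": sex, "breed_class": breed, "parity_class": parity,
        "calving_ease": ease,
        "birth_weight": np.where(missing_bw, np.nan, np.round(birth_weight, 1)),
        "hutch_exit_datetime": [
            (t0 + pd.Timedelta(hours=int(h))).isoformat() for h in exit_hours],
        "pen_id": [f"P{p + 1}" for p in pen],
        "group_id": [f"G{g + 1:02d}" for g in group],
        "feeder_system": feeder,
        "died": died, "sold": sold, "returned_to_hutch": returned,
        "treated_b2g": rt.random(n) < config.treat_b2g_prob,
        "treated_g2e": rt.random(n) < config.treat_g2e_prob,
    })
    truth = pd.DataFrame({
        "calf_id": calf_ids, "prop_b2g": props_b2g,
        "cat_b2g": cats_b2g.astype(str), "dlwg_b2g": dlwg_b2g,
        "lh_weight": lh_weight, "prop_g2e": g2e_props,
        "slope_g2e": slope_true, "avg_cmr": avg_cmr,
        "season": [season_of_birth(b) for b in births],
    })
    return {
        "roster": roster,
        "weights": pd.DataFrame(weight_rows),
        "health": pd.DataFrame(health_rows),
        "milk": pd.DataFrame(milk_rows),
        "truth": truth,
        "climate": climate,
    }


def generate_study(outdir, seed: int = 0,
                   climate_config: ClimateGenConfig | None = None,
                   cohort_config: CohortGenConfig | None = None,
                   exclusions: ExclusionPlan | None = ExclusionPlan()) -> dict:
    """Write a complete synthetic study to ``outdir`` as CSV files.

    Files: ``climate.csv``, ``roster.csv``, ``weights.csv``,
    ``health.csv``, ``milk.csv`` (plus ``truth.csv`` for reference); all
    are readable by the ingestion pipeline without modification.  With the
    default :class:`ExclusionPlan` the roster holds 299 calves of which
    271 are hutch-phase eligible and 221 group-phase eligible.
    """
    climate_config = climate_config or ClimateGenConfig()
    if cohort_config is None:
        n = 271
        if exclusions is not None:
            n += (exclusions.missing_birthweight + exclusions.overage)
        cohort_config = CohortGenConfig(n_calves=n)
    climate = generate_climate(climate_config, rng=_streams(seed)["climate"])
    bundle = generate_cohort(cohort_config, climate=climate, seed=seed,
                             exclusions=exclusions)
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name in ("climate", "roster", "weights", "health", "milk", "truth"):
        path = os.path.join(outdir, f"{name}.csv")
        frame = bundle[name].copy()
        if name == "climate":
            frame["timestamp"] = pd.to_datetime(
                frame["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
            for col in ("air_temp", "rel_humidity", "wind_speed"):
                frame[col] = frame[col].round(3)
        frame.to_csv(path, index=False, float_format="%.6g")
        paths[name] = path
    return paths
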