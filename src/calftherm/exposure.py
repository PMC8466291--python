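"""Age-dependent lower critical temperature and cold-exposure statistics.

The lower critical temperature (LCT) is the environmental temperature
below which a calf must raise metabolic heat production to hold its core
temperature.  Two definitions are provided:

* a *physiological* form,

      T_lc = (T_r + H'_e,min * I_e) - H_min * (I_t + I_e)

  in terms of rectal temperature, external (coat) and tissue insulation,
  minimum evaporative heat loss and thermoneutral heat production; and

* a simplified *age schedule* used for routine exposure scoring: 15 °C at
  birth (day 0), declining by 0.5 °C per day of age.

The exposure statistic for a calf over a housing phase is the proportion
of the phase's available hours during which the hourly effective
temperature fell strictly below the calf's age-related LCT.  Age advances
at 24-hour anniversaries of the birth timestamp, so day boundaries are
calf-relative, not calendar midnights.  Hours missing from the climate
series are excluded from both numerator and denominator.

Proportions are banded into the study's four phase-specific categories
(:data:`B2G_SCHEME`, :data:`G2E_SCHEME`); values are rounded half-up to
two decimals first, which closes the gaps between printed category bounds
(e.g. 0.325 -> 0.33).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

__all__ = [
    "AgeLCTSchedule",
    "PhysiologicalLCTParams",
    "CategoryScheme",
    "ExposureSummary",
    "B2G_SCHEME",
    "G2E_SCHEME",
    "lct_for_age",
    "physiological_lct",
    "exposure_proportion",
    "categorise_exposure",
]


@dataclass(frozen=True)
class AgeLCTSchedule:
    """Linear-in-age LCT schedule: ``lct_at_birth - daily_decline * age``.

    ``floor`` optionally clips the schedule from below; by default none is
    applied (over a ~30-day study horizon the schedule stays near 0 °C).
    """

    lct_at_birth: float = 15.0
    daily_decline: float = 0.5
    floor: float | None = None

    def __post_init__(self):
        if self.daily_decline < 0:
            raise ValueError("daily_decline must be >= 0")


@dataclass(frozen=True)
class PhysiologicalLCTParams:
    """Symbols of the physiological LCT equation.

    rectal_temp (°C); external_insulation and tissue_insulation
    (°C·m²/W); min_evaporative_heat_loss and thermoneutral_heat_production
    (W/m²).  All insulations and heat terms must be non-negative.
    """

    rectal_temp: float
    external_insulation: float
    min_evaporative_heat_loss: float
    thermoneutral_heat_production: float
    tissue_insulation: float

    def __post_init__(self):
        if self.external_insulation < 0 or self.tissue_insulation < 0:
            raise ValueError("insulation terms must be >= 0")
        if (self.min_evaporative_heat_loss < 0
                or self.thermoneutral_heat_production < 0):
            raise ValueError("heat terms must be >= 0")


@dataclass(frozen=True)
class CategoryScheme:
    """Four ordered exposure bands on [0, 1] for one housing phase.

    ``upper_cents`` are the inclusive upper bounds of the first three bands
    expressed in hundredths (the printed cut-points are two-decimal
    values); the fourth band runs to 1.  ``labels`` name the bands in
    increasing-exposure order; the first label is the modelling reference
    level.
    """

    phase: str
    upper_cents: tuple[int, int, int]
    labels: tuple[str, str, str, str]

    def __post_init__(self):
        if not (0 <= self.upper_cents[0] < self.upper_cents[1]
                < self.upper_cents[2] <= 100):
            raise ValueError("category bounds must be ordered within [0, 100]")


B2G_SCHEME = CategoryScheme(
    phase="B2G",
    upper_cents=(32, 58, 96),
    labels=("<=0.32", "0.33-0.58", "0.59-0.96", ">=0.97"),
)
G2E_SCHEME = CategoryScheme(
    phase="G2E",
    upper_cents=(1, 6, 27),
    labels=("<=0.01", "0.02-0.06", "0.07-0.27", ">=0.28"),
)


@dataclass(frozen=True)
class ExposureSummary:
    """Per-calf, per-phase cold-exposure summary."""

    calf_id: str
    phase: str
    hours_below: int
    total_hours: int
    proportion: float
    category: str

    def __post_init__(self):
        if not 0 <= self.hours_below <= self.total_hours:
            raise ValueError("hours_below must lie in [0, total_hours]")
        if self.total_hours <= 0:
            raise ValueError("total_hours must be positive")


def lct_for_age(age_days, schedule: AgeLCTSchedule | None = None):
    """LCT (°C) at a whole-day age under an :class:`AgeLCTSchedule`.

    Vectorised over ``age_days``; negative ages raise ``ValueError``.
    """
    schedule = schedule or AgeLCTSchedule()
    age = np.asarray(age_days)
    if np.any(age < 0):
        raise ValueError("age_days must be >= 0")
    lct = schedule.lct_at_birth - schedule.daily_decline * age
    if schedule.floor is not None:
        lct = np.maximum(lct, schedule.floor)
    return float(lct) if lct.ndim == 0 else lct


def physiological_lct(params: PhysiologicalLCTParams) -> float:
    """Evaluate the physiological LCT equation (°C)."""
    return (
        params.rectal_temp
        + params.min_evaporative_heat_loss * params.external_insulation
        - params.thermoneutral_heat_production
        * (params.tissue_insulation + params.external_insulation)
    )


def categorise_exposure(proportion: float, scheme: CategoryScheme) -> str:
    """Band a proportion into one of the scheme's four categories.

    The proportion is first rounded half-up to two decimals so every real
    in [0, 1] maps to exactly one band despite the gap between printed
    cut-points.
    """
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must lie in [0, 1]")
    # round half-up on hundredths (Python's round() is half-even)
    cents = int(np.floor(proportion * 100 + 0.5))
    for bound, label in zip(scheme.upper_cents, scheme.labels):
        if cents <= bound:
            return label
    return scheme.labels[3]


def hours_below_lct(et_values: np.ndarray, age_hours: np.ndarray,
                    schedule: AgeLCTSchedule) -> int:
    """Count hours with ET strictly below the age-related LCT.

    ``age_hours`` holds each hour's offset from birth in whole hours; age
    in days is ``age_hours // 24``.  Equality is *not* below (strict
    comparison).
    """
    lct = lct_for_age(np.asarray(age_hours) // 24, schedule)
    return int(np.sum(np.asarray(et_values) < lct))


def exposure_proportion(
    birth: datetime,
    window_start: datetime,
    window_end: datetime,
    et: pd.DataFrame,
    schedule: AgeLCTSchedule | None = None,
    scheme: CategoryScheme = B2G_SCHEME,
    calf_id: str = "",
) -> ExposureSummary:
    """Proportion of available hours below the age-related LCT.

    ``et`` is an effective-temperature frame (``timestamp``,
    ``effective_temp``).  Hours ``h`` with ``window_start <= h <
    window_end`` present in the frame are counted; an hour is below iff
    ``ET(h) < lct_for_age(floor((h - birth) / 24 h))``.  Raises if the
    window precondition fails or no hours are available.
    """
    schedule = schedule or AgeLCTSchedule()
    if window_start < birth:
        raise ValueError("window_start must be >= birth")
    if window_end <= window_start:
        raise ValueError("window_end must be after window_start")

    ts = pd.to_datetime(et["timestamp"])
    mask = (ts >= window_start) & (ts < window_end)
    total = int(mask.sum())
    if total == 0:
        raise ValueError(
            f"no climate hours available in window for calf {calf_id!r}")

    age_hours = ((ts[mask] - pd.Timestamp(birth))
                 // pd.Timedelta(hours=1)).to_numpy()
    below = hours_below_lct(et.loc[mask.to_numpy(), "effective_temp"].to_numpy(),
                            age_hours, schedule)
    proportion = below / total
    return ExposureSummary(
        calf_id=calf_id,
        phase=scheme.phase,
        hours_below=below,
        total_hours=total,
        proportion=proportion,
        category=categorise_exposure(proportion, scheme),
    )
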