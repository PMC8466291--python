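"""Calf-level study records: seasons, health status, eligibility filters.

The cohort tables are ordinary :class:`pandas.DataFrame` objects using the
documented column dictionary (see :data:`ROSTER_COLUMNS` etc.).  Health is
scored by the Wisconsin method restricted to five aspects (rectal
temperature, ocular discharge, nasal discharge, head/ear position, cough),
each 0–3, summed to an overall score of 0–15; faecal consistency is not
scored because group-housed calves cannot be matched to their faeces.

Status rules (rectal score r, overall score s, s >= r):

=============  =========================================
Healthy        r <= 2 and s <= 3
Intermediate   r <= 2 and s == 4
Diseased       r == 3 (any s), or s >= 5
=============  =========================================

Eligibility: the hutch phase (B2G) requires a recorded birth weight and a
hutch-exit age of at most 14 whole days; the group phase (G2E) further
excludes calves that died or were euthanised, were sold, returned to an
individual hutch, lack a complete daily milk-intake record, or have fewer
than two group-pen weights (a growth slope needs two points).  When a calf
fails several rules only the first, in the order above, is logged, so the
per-reason exclusion counts are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalfRecord",
    "season_of_birth",
    "classify_health",
    "signs_of_disease_ever",
    "filter_b2g",
    "filter_g2e",
    "hutch_exit_age_days",
    "HEALTH_STATUSES",
    "ROSTER_COLUMNS",
    "WEIGHT_COLUMNS",
    "HEALTH_COLUMNS",
    "MILK_COLUMNS",
]

HEALTH_STATUSES = ("Healthy", "Intermediate", "Diseased")

SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

ROSTER_COLUMNS = [
    "calf_id", "birth_datetime", "sex", "breed_class", "parity_class",
    "calving_ease", "birth_weight", "hutch_exit_datetime", "pen_id",
    "group_id", "feeder_system", "died", "sold", "returned_to_hutch",
    "treated_b2g", "treated_g2e",
]
WEIGHT_COLUMNS = ["calf_id", "datetime", "weight", "weighing_number"]
HEALTH_COLUMNS = [
    "calf_id", "datetime", "rectal_score", "ocular_score", "nasal_score",
    "ear_score", "cough_score", "overall_score",
]
MILK_COLUMNS = ["calf_id", "date", "milk_volume", "cmr_mass"]


@dataclass
class CalfRecord:
    """One enrolled calf (typed mirror of a roster row)."""

    calf_id: str
    birth_datetime: datetime
    sex: str
    breed_class: str
    parity_class: str
    calving_ease: str
    birth_weight: float | None = None
    hutch_exit_datetime: datetime | None = None
    pen_id: str | None = None
    group_id: str | None = None
    feeder_system: str | None = None
    died: bool = False
    sold: bool = False
    returned_to_hutch: bool = False
    treated_b2g: bool = False
    treated_g2e: bool = False

    def __post_init__(self):
        if (self.hutch_exit_datetime is not None
                and self.hutch_exit_datetime <= self.birth_datetime):
            raise ValueError("hutch_exit_datetime must be after birth")
        if self.birth_weight is not None and not self.birth_weight > 0:
            raise ValueError("birth_weight must be positive")


def season_of_birth(birth_date: date | datetime | str) -> str:
    """Meteorological season (winter/spring/summer/autumn) of a birth date."""
    month = pd.Timestamp(birth_date).month
    return SEASONS[month]


def classify_health(rectal_score: int, overall_score: int) -> str:
    """Health status from the rectal component and overall Wisconsin score."""
    if not 0 <= rectal_score <= 3:
        raise ValueError("rectal_score must be in 0..3")
    if not 0 <= overall_score <= 15:
        raise ValueError("overall_score must be in 0..15")
    if overall_score < rectal_score:
        raise ValueError("overall_score cannot be below its rectal component")
    if rectal_score == 3 or overall_score >= 5:
        return "Diseased"
    if overall_score == 4:
        return "Intermediate"
    return "Healthy"


def signs_of_disease_ever(statuses: Sequence[str]) -> str:
    """'yes' iff any status in the sequence is Intermediate or Diseased."""
    statuses = list(statuses)
    if not statuses:
        raise ValueError("empty status sequence")
    unknown = set(statuses) - set(HEALTH_STATUSES)
    if unknown:
        raise ValueError(f"unknown health status: {sorted(unknown)}")
    return "yes" if any(s != "Healthy" for s in statuses) else "no"


def hutch_exit_age_days(birth, exit_dt) -> int:
    """Whole-day age at hutch exit: floor((exit - birth) / 24 h)."""
    return int((pd.Timestamp(exit_dt) - pd.Timestamp(birth))
               // pd.Timedelta(days=1))


def _log(entries: list, calf_id, phase: str, reason: str) -> None:
    entries.append({"calf_id": calf_id, "phase": phase, "reason": reason})


def filter_b2g(roster: pd.DataFrame, max_exit_age: int = 14
               ) -> tuple[list, pd.DataFrame]:
    """Hutch-phase eligibility: recorded birth weight, exit age <= 14 d.

    Returns (eligible calf ids in roster order, exclusion-log frame with
    columns calf_id/phase/reason, one row per excluded calf, first failing
    rule only).
    """
    eligible, log = [], []
    births = pd.to_datetime(roster["birth_datetime"])
    exits = pd.to_datetime(roster["hutch_exit_datetime"])
    for i, row in roster.iterrows():
        if pd.isna(row["birth_weight"]):
            _log(log, row["calf_id"], "B2G", "no birthweight")
            continue
        age = hutch_exit_age_days(births[i], exits[i])
        if age > max_exit_age:
            _log(log, row["calf_id"], "B2G", f"age > {max_exit_age} d")
            continue
        eligible.append(row["calf_id"])
    return eligible, pd.DataFrame(log, columns=["calf_id", "phase", "reason"])


def _milk_complete(milk_dates: set, entry: pd.Timestamp,
                   last_weigh: pd.Timestamp) -> bool:
    wanted = pd.date_range(entry.normalize(), last_weigh.normalize(), freq="D")
    return all(d in milk_dates for d in wanted)


def filter_g2e(
    b2g_eligible: Iterable,
    roster: pd.DataFrame,
    weights: pd.DataFrame,
    milk: pd.DataFrame,
) -> tuple[list, pd.DataFrame]:
    """Group-phase eligibility on top of the hutch-phase eligible set.

    Exclusion order: died/euthanised, sold, returned to hutch, incomplete
    daily milk record (pen entry to last weighing, calendar days), fewer
    than two group-pen weights.
    """
    eligible, log = [], []
    roster = roster.set_index("calf_id", drop=False)
    weights = weights.assign(datetime=pd.to_datetime(weights["datetime"]))
    wgt_by_calf = dict(tuple(weights.groupby("calf_id")))
    milk = milk.assign(date=pd.to_datetime(milk["date"]))
    milk_dates = {cid: set(g["date"].dt.normalize())
                  for cid, g in milk.groupby("calf_id")}

    for cid in b2g_eligible:
        row = roster.loc[cid]
        if bool(row["died"]):
            _log(log, cid, "G2E", "died or euthanised")
            continue
        if bool(row["sold"]):
            _log(log, cid, "G2E", "sold")
            continue
        if bool(row["returned_to_hutch"]):
            _log(log, cid, "G2E", "returned to hutch")
            continue
        w = wgt_by_calf.get(cid)
        n_weights = 0 if w is None else len(w)
        entry = pd.Timestamp(row["hutch_exit_datetime"])
        if n_weights >= 1:
            last_weigh = w["datetime"].max()
            if not _milk_complete(milk_dates.get(cid, set()), entry, last_weigh):
                _log(log, cid, "G2E", "incomplete milk data")
                continue
        if n_weights < 2:
            _log(log, cid, "G2E", "fewer than two group-pen weights")
            continue
        eligible.append(cid)
    return eligible, pd.DataFrame(log, columns=["calf_id", "phase", "reason"])
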