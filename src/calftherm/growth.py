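"""Daily liveweight gain (DLWG) and milk-replacer intake summaries.

DLWG (kg/d) is defined two ways, matching how each housing phase is
weighed:

* **interval** — (end weight − start weight) / days between the two
  weighings; used for the hutch phase, where a calf is weighed exactly
  twice (birth and hutch exit);
* **slope** — the ordinary-least-squares slope of weight (kg) on age
  (days) over repeated weighings; used for the group phase, where growth
  rate may change over time.  On exactly two points the slope reduces to
  the interval rate.

Calf milk replacer (CMR) is reconstituted at a weight-per-volume
concentration, so a daily allowance in litres converts to powder mass as
``volume (L) x concentration (%) x 10 g/(L·%)`` — e.g. 6 L/d at 15% is
900 g/d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthRecord",
    "dlwg_interval",
    "dlwg_slope",
    "avg_daily_cmr",
    "cmr_mass_from_volume",
]


@dataclass(frozen=True)
class GrowthRecord:
    """One calf's growth-rate summary for one phase."""

    calf_id: str
    phase: str
    dlwg: float
    method: str  # "interval" | "slope"
    n_points: int
    span_days: float

    def __post_init__(self):
        if self.span_days <= 0:
            raise ValueError("span_days must be positive")
        if self.method == "interval" and self.n_points != 2:
            raise ValueError("interval DLWG uses exactly two weighings")
        if self.method == "slope" and self.n_points < 2:
            raise ValueError("slope DLWG needs at least two weighings")


def dlwg_interval(weight_start: float, weight_end: float, days: float) -> float:
    """Interval growth rate (kg/d) between two weighings ``days`` apart."""
    if days <= 0:
        raise ValueError("days must be positive")
    return (weight_end - weight_start) / days


def dlwg_slope(points: Sequence[tuple[float, float]]) -> float:
    """OLS slope of weight (kg) on age (days) over repeated weighings.

    ``points`` is a sequence of (age_days, weight_kg) pairs; at least two
    points with at least two distinct ages are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (age, weight) points")
    age, weight = pts[:, 0], pts[:, 1]
    if np.ptp(age) == 0:
        raise ValueError("ages are all identical; slope undefined")
    age_c = age - age.mean()
    return float(np.dot(age_c, weight - weight.mean()) / np.dot(age_c, age_c))


def avg_daily_cmr(records: Iterable | pd.DataFrame, n_days: float) -> float:
    """Average daily CMR intake (g/d): total mass over the phase / n_days.

    ``records`` may be a milk-intake frame (column ``cmr_mass``) or any
    iterable of objects/mappings with a ``cmr_mass`` attribute or key.  No
    records means zero consumption.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if isinstance(records, pd.DataFrame):
        total = float(records["cmr_mass"].sum()) if len(records) else 0.0
    else:
        total = 0.0
        for rec in records:
            if hasattr(rec, "cmr_mass"):
                total += float(rec.cmr_mass)
            else:
                total += float(rec["cmr_mass"])
    return total / n_days


def cmr_mass_from_volume(volume: float, concentration: float = 15.0) -> float:
    """Powder mass (g/d) from a reconstituted-milk volume (L/d).

    ``concentration`` is weight-per-volume in % (g per 100 mL); 15% means
    150 g of powder per litre of mixed milk.
    """
    if volume < 0:
        raise ValueError("volume must be non-negative")
    if not 0 < concentration <= 100:
        raise ValueError("concentration must lie in (0, 100] %")
    return volume * concentration * 10.0
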