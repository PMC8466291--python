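"""Hourly barn-climate ingestion, validation and effective temperature.

The climatic environment inside naturally ventilated calf housing is
described by three hourly sensor channels: air temperature ``t`` (°C),
relative humidity ``ur`` (%) and wind speed ``v`` (m/s).  They are combined
into a single *effective temperature* (ET, °C) — a perceived-temperature
index in which humidity and air movement amplify the sensation of cold:

    ET = 37 - (37 - t) / [0.68 - 0.0014*ur + 1/(1.76 + 1.4*v**0.75)]
         - 0.29*t*(1 - ur/100)

(the wind-adjusted formulation of Suping's effective-temperature index).
ET has a fixed point at body-like conditions: ET(37, 100, v) = 37 for any
wind speed, because both correction terms vanish there.

Hourly series are represented as :class:`pandas.DataFrame` objects with
columns ``timestamp`` (hourly, treated as the start of the hour, local
naive time), ``air_temp``, ``rel_humidity`` and ``wind_speed``.  Timestamps
must be unique and sorted; gaps of at most :data:`MAX_FILL_HOURS` hours are
forward-filled and flagged, longer gaps are left absent (downstream
exposure statistics exclude absent hours from both numerator and
denominator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ClimateDialect",
    "ValidationReport",
    "read_climate",
    "effective_temperature",
    "hourly_et_series",
    "MAX_FILL_HOURS",
]

#: longest run of missing hours that is forward-filled rather than left absent
MAX_FILL_HOURS = 3

REQUIRED_FIELDS = ("timestamp", "air_temp", "rel_humidity", "wind_speed")


@dataclass
class ClimateDialect:
    """Column mapping for a delimited climate file.

    Attributes name the columns in the source file that hold each required
    field; ``timestamp_format`` may give an explicit ``strptime`` pattern
    (default: ISO-8601 as parsed by pandas).
    """

    timestamp: str = "timestamp"
    air_temp: str = "air_temp"
    rel_humidity: str = "rel_humidity"
    wind_speed: str = "wind_speed"
    timestamp_format: str | None = None
    delimiter: str = ","


@dataclass
class ValidationReport:
    """Row-level outcome of climate validation.

    ``dropped`` lists (row index, reason) pairs for rows excluded from the
    series; ``filled`` lists ISO timestamps of hours that were forward-filled
    across short gaps; ``n_input`` / ``n_output`` are row counts before and
    after validation.
    """

    n_input: int = 0
    n_output: int = 0
    dropped: list[tuple[int, str]] = field(default_factory=list)
    filled: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.dropped and not self.filled

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def effective_temperature(air_temp, rel_humidity, wind_speed):
    """Wind-adjusted effective temperature (°C).

    Accepts scalars or numpy arrays (broadcast).  Raises ``ValueError``
    for relative humidity outside [0, 100] or negative wind speed.
    """
    t = np.asarray(air_temp, dtype=float)
    ur = np.asarray(rel_humidity, dtype=float)
    v = np.asarray(wind_speed, dtype=float)
    if np.any(ur < 0) or np.any(ur > 100):
        raise ValueError("relative humidity must lie in [0, 100] %")
    if np.any(v < 0):
        raise ValueError("wind speed must be non-negative")
    denom = 0.68 - 0.0014 * ur + 1.0 / (1.76 + 1.4 * v**0.75)
    et = 37.0 - (37.0 - t) / denom - 0.29 * t * (1.0 - ur / 100.0)
    if et.ndim == 0:
        return float(et)
    return et


def hourly_et_series(series: pd.DataFrame) -> pd.DataFrame:
    """Element-wise ET over a validated hourly series.

    Returns a frame with columns ``timestamp`` and ``effective_temp``,
    one row per input hour (empty in → empty out).
    """
    if series.empty:
        return pd.DataFrame({"timestamp": pd.Series([], dtype="datetime64[ns]"),
                             "effective_temp": pd.Series([], dtype=float)})
    et = effective_temperature(
        series["air_temp"].to_numpy(),
        series["rel_humidity"].to_numpy(),
        series["wind_speed"].to_numpy(),
    )
    return pd.DataFrame({"timestamp": series["timestamp"].to_numpy(),
                         "effective_temp": np.atleast_1d(et)})


def validate_climate(frame: pd.DataFrame, dialect: ClimateDialect | None = None
                     ) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate an in-memory climate table.

    Applies the row-level rules (parseable timestamp, RH in [0, 100],
    non-negative wind, finite air temperature), de-duplicates identical
    rows, raises on duplicate timestamps with conflicting values, sorts
    ascending, and forward-fills gaps of at most :data:`MAX_FILL_HOURS`
    hours (flagged in the report).
    """
    dialect = dialect or ClimateDialect()
    report = ValidationReport(n_input=len(frame))
    if frame.empty:
        raise ValueError("climate file contains no data rows")

    renames = {dialect.timestamp: "timestamp", dialect.air_temp: "air_temp",
               dialect.rel_humidity: "rel_humidity", dialect.wind_speed: "wind_speed"}
    missing = [src for src in renames if src not in frame.columns]
    if missing:
        raise ValueError(f"climate file missing column(s): {missing}")
    df = frame.rename(columns=renames)[list(REQUIRED_FIELDS)].copy()

    ts = pd.to_datetime(df["timestamp"], format=dialect.timestamp_format,
                        errors="coerce")
    bad_ts = ts.isna()
    # hours whose rows are dropped stay absent: they must not be re-created
    # by gap filling.  For an unparseable timestamp the intended hour is
    # inferred when its neighbours bracket exactly one missing hour.
    rejected_hours: set = set()
    positions = list(df.index)
    for idx in df.index[bad_ts]:
        pos = positions.index(idx)
        if 0 < pos < len(positions) - 1:
            prev_ts = ts[positions[pos - 1]]
            next_ts = ts[positions[pos + 1]]
            if (pd.notna(prev_ts) and pd.notna(next_ts)
                    and next_ts - prev_ts == pd.Timedelta(hours=2)):
                rejected_hours.add(prev_ts + pd.Timedelta(hours=1))
        report.dropped.append((int(idx), "unparseable timestamp"))
    df = df[~bad_ts].assign(timestamp=ts[~bad_ts])

    for col in ("air_temp", "rel_humidity", "wind_speed"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    checks = [
        (~np.isfinite(df["air_temp"]), "non-numeric or missing air temperature"),
        ((df["rel_humidity"] < 0) | (df["rel_humidity"] > 100)
         | ~np.isfinite(df["rel_humidity"]), "relative humidity outside [0, 100]"),
        ((df["wind_speed"] < 0) | ~np.isfinite(df["wind_speed"]),
         "negative or missing wind speed"),
    ]
    bad = pd.Series(False, index=df.index)
    for mask, reason in checks:
        for idx in df.index[mask & ~bad]:
            report.dropped.append((int(idx), reason))
        bad |= mask
    rejected_hours.update(df.loc[bad, "timestamp"])
    df = df[~bad]
    if df.empty:
        raise ValueError("no valid climate rows after validation")

    df = df.drop_duplicates()  # identical repeated rows are harmless
    dup = df["timestamp"].duplicated(keep=False)
    if dup.any():
        stamps = df.loc[dup, "timestamp"].dt.strftime("%Y-%m-%d %H:%M").unique()
        raise ValueError(
            "duplicate timestamps with conflicting values: " + ", ".join(stamps[:5]))
    df = df.sort_values("timestamp").reset_index(drop=True)

    # forward-fill short gaps only; long gaps stay absent
    full = pd.date_range(df["timestamp"].iloc[0], df["timestamp"].iloc[-1], freq="h")
    if len(full) > len(df):
        reindexed = df.set_index("timestamp").reindex(full)
        missing_mask = reindexed["air_temp"].isna()
        gap_id = (~missing_mask).cumsum()
        gap_len = missing_mask.groupby(gap_id).transform("sum")
        fillable = (missing_mask & (gap_len <= MAX_FILL_HOURS)
                    & ~reindexed.index.isin(list(rejected_hours)))
        filled = reindexed.ffill()
        reindexed[fillable] = filled[fillable]
        report.filled = [ts.isoformat() for ts in reindexed.index[fillable]]
        reindexed = reindexed.dropna()
        df = reindexed.rename_axis("timestamp").reset_index()

    report.n_output = len(df)
    return df, report


def read_climate(path, dialect: ClimateDialect | None = None
                 ) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate an hourly climate CSV.

    Returns the validated series and a :class:`ValidationReport`.  Hard
    errors (empty file, missing columns, conflicting duplicate timestamps)
    raise ``ValueError``; row-level problems are dropped and reported.
    """
    dialect = dialect or ClimateDialect()
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"climate file {path} is empty") from exc
    return validate_climate(raw, dialect)
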