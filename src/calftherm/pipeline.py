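"""End-to-end orchestration: ingest -> ET -> exposure -> growth -> models.

Each phase run reads the five study CSVs (climate, roster, weights,
health scores, milk intakes), applies the eligibility filters, assembles
the per-calf analysis table (growth rate, cold-exposure category and
husbandry covariates), fits the screening / backward-elimination model
chain, and writes every intermediate artefact to the output directory so
any stage can be inspected or re-run:

========================  ====================================================
``et.csv``                hourly effective temperature
``climate_validation.json``  row-level climate QC report
``<phase>_exclusions.csv``   exclusion log (calf, phase, first failing rule)
``<phase>_table.csv``        analysis table, one row per eligible calf
``<phase>_model.csv``        final-model coefficient table
``<phase>_trace.json``       screening p-values and elimination trace
``<phase>_tukey_<term>.csv`` pairwise contrasts of retained factors
========================  ====================================================
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from calftherm import __version__
from calftherm.climate import ClimateDialect, hourly_et_series, read_climate
from calftherm.cohort import (
    classify_health,
    filter_b2g,
    filter_g2e,
    hutch_exit_age_days,
    season_of_birth,
    signs_of_disease_ever,
)
from calftherm.exposure import (
    B2G_SCHEME,
    G2E_SCHEME,
    AgeLCTSchedule,
    CategoryScheme,
    exposure_proportion,
)
from calftherm.growth import avg_daily_cmr, dlwg_interval, dlwg_slope
from calftherm.models import DlwgModel, DlwgResults

__all__ = [
    "PipelineConfig",
    "PhaseOutput",
    "load_config",
    "default_config",
    "run_b2g",
    "run_g2e",
    "report",
    "descriptive_table",
]

logger = logging.getLogger("calftherm")

B2G_CANDIDATES = ("prop_cat", "birth_weight", "exit_age", "sex",
                  "breed_class", "parity_class", "calving_ease", "season",
                  "treated_b2g")
G2E_CANDIDATES = ("prop_cat", "birth_weight", "entry_age", "avg_cmr", "sex",
                  "breed_class", "parity_class", "calving_ease", "season",
                  "treated_b2g", "treated_g2e", "signs_disease")
G2E_RANDOM = ("group_id", "pen_id", "feeder_system")


@dataclass
class PipelineConfig:
    """File locations, schedule/scheme parameters and model thresholds."""

    climate_path: str = "climate.csv"
    roster_path: str = "roster.csv"
    weights_path: str = "weights.csv"
    health_path: str = "health.csv"
    milk_path: str = "milk.csv"
    outdir: str = "out"
    dialect: ClimateDialect = field(default_factory=ClimateDialect)
    lct_schedule: AgeLCTSchedule = field(default_factory=AgeLCTSchedule)
    b2g_scheme: CategoryScheme = B2G_SCHEME
    g2e_scheme: CategoryScheme = G2E_SCHEME
    alpha_screen: float = 0.20
    alpha_retain: float = 0.05
    max_exit_age: int = 14
    seed: int = 0
    verbosity: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PhaseOutput:
    """Everything one phase run produced."""

    table: pd.DataFrame
    results: DlwgResults
    tukey: dict
    exclusions: pd.DataFrame
    paths: dict


def default_config(study_dir: str, outdir: str | None = None,
                   **overrides) -> PipelineConfig:
    """Config pointing at a `generate_study` directory layout."""
    cfg = PipelineConfig(
        climate_path=os.path.join(study_dir, "climate.csv"),
        roster_path=os.path.join(study_dir, "roster.csv"),
        weights_path=os.path.join(study_dir, "weights.csv"),
        health_path=os.path.join(study_dir, "health.csv"),
        milk_path=os.path.join(study_dir, "milk.csv"),
        outdir=outdir or os.path.join(study_dir, "out"),
    )
    return dataclasses.replace(cfg, **overrides)


def load_config(path: str) -> PipelineConfig:
    """Read a YAML pipeline config (keys mirror PipelineConfig fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in raw.items():
        if key == "dialect":
            kwargs[key] = ClimateDialect(**value)
        elif key == "lct_schedule":
            kwargs[key] = AgeLCTSchedule(**value)
        elif key in ("b2g_scheme", "g2e_scheme"):
            kwargs[key] = CategoryScheme(
                phase=value["phase"],
                upper_cents=tuple(value["upper_cents"]),
                labels=tuple(value["labels"]))
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _setup(config: PipelineConfig):
    logging.basicConfig(level=config.verbosity)
    os.makedirs(config.outdir, exist_ok=True)
    logger.info("calftherm %s | config %s | seed %d", __version__,
                config.config_hash(), config.seed)


def _load_inputs(config: PipelineConfig):
    for name, path in (("climate", config.climate_path),
                       ("roster", config.roster_path),
                       ("weights", config.weights_path),
                       ("health", config.health_path),
                       ("milk", config.milk_path)):
        if not os.path.exists(path):
            raise FileNotFoundError(f"required input {name!r} not found: {path}")
    climate, vreport = read_climate(config.climate_path, config.dialect)
    et = hourly_et_series(climate)
    roster = pd.read_csv(config.roster_path)
    for col in ("calf_id", "birth_datetime", "hutch_exit_datetime",
                "birth_weight"):
        if col not in roster.columns:
            raise ValueError(f"roster file lacks required column {col!r}")
    roster["birth_datetime"] = pd.to_datetime(roster["birth_datetime"])
    roster["hutch_exit_datetime"] = pd.to_datetime(roster["hutch_exit_datetime"])
    weights = pd.read_csv(config.weights_path)
    weights["datetime"] = pd.to_datetime(weights["datetime"])
    health = pd.read_csv(config.health_path)
    health["datetime"] = pd.to_datetime(health["datetime"])
    milk = pd.read_csv(config.milk_path)
    milk["date"] = pd.to_datetime(milk["date"])

    et_path = os.path.join(config.outdir, "et.csv")
    et.to_csv(et_path, index=False, float_format="%.6g")
    vreport.to_json(os.path.join(config.outdir, "climate_validation.json"))
    return climate, et, roster, weights, health, milk


def _covariates(row) -> dict:
    return {
        "sex": row["sex"], "breed_class": row["breed_class"],
        "parity_class": row["parity_class"],
        "calving_ease": row["calving_ease"],
        "season": season_of_birth(row["birth_datetime"]),
        "treated_b2g": "yes" if row["treated_b2g"] else "no",
    }


def _fit_phase(table, candidates, random_terms, config) -> DlwgResults:
    present = [c for c in candidates if c in table.columns]
    model = DlwgModel.from_dataframe(
        table, response="dlwg", candidate_terms=present,
        random_terms=random_terms, alpha_screen=config.alpha_screen,
        alpha_retain=config.alpha_retain)
    return model.fit()


def _emit(phase: str, table, results, exclusions, config) -> tuple[dict, dict]:
    paths = {}

    def _save(name, frame):
        path = os.path.join(config.outdir, f"{phase}_{name}.csv")
        frame.to_csv(path, index=False, float_format="%.6g")
        paths[name] = path

    _save("table", table)
    _save("exclusions", exclusions)
    _save("model", results.to_frame())
    trace_path = os.path.join(config.outdir, f"{phase}_trace.json")
    screening = (results.screening.to_dict(orient="records")
                 if results.screening is not None else [])
    with open(trace_path, "w") as fh:
        json.dump({"version": __version__, "seed": config.seed,
                   "config_hash": config.config_hash(),
                   "screening": screening, "trace": results.trace,
                   "retained": results.retained}, fh, indent=2, default=str)
    paths["trace"] = trace_path

    tukey = {}
    for term in results.retained:
        if results.model.is_factor(term) and table[term].nunique() >= 3:
            contrasts = results.tukey(term)
            tukey[term] = contrasts
            _save(f"tukey_{term}", contrasts)
    return tukey, paths


def build_b2g_table(et, roster, weights, config) -> tuple[pd.DataFrame,
                                                          pd.DataFrame]:
    """Analysis table for the hutch phase (one row per eligible calf)."""
    eligible, exclusions = filter_b2g(roster, config.max_exit_age)
    roster_idx = roster.set_index("calf_id", drop=False)
    first_weight = (weights.sort_values(["calf_id", "datetime"])
                    .groupby("calf_id").first())
    rows = []
    for cid in eligible:
        row = roster_idx.loc[cid]
        birth = row["birth_datetime"]
        exit_dt = row["hutch_exit_datetime"]
        age = hutch_exit_age_days(birth, exit_dt)
        if cid not in first_weight.index:
            raise ValueError(f"calf {cid!r} has no hutch-exit weight record")
        lh_weight = float(first_weight.loc[cid, "weight"])
        summary = exposure_proportion(birth, birth, exit_dt, et,
                                      config.lct_schedule,
                                      scheme=config.b2g_scheme, calf_id=cid)
        rows.append({
            "calf_id": cid,
            "dlwg": dlwg_interval(float(row["birth_weight"]), lh_weight, age),
            "prop_cat": summary.category,
            "proportion": summary.proportion,
            "hours_below": summary.hours_below,
            "total_hours": summary.total_hours,
            "birth_weight": float(row["birth_weight"]),
            "exit_age": float(age),
            **_covariates(row),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["prop_cat"] = pd.Categorical(
            table["prop_cat"], categories=list(config.b2g_scheme.labels))
    return table, exclusions


def run_b2g(config: PipelineConfig) -> PhaseOutput:
    """Hutch-phase analysis: table, final model, post-hoc contrasts."""
    _setup(config)
    _, et, roster, weights, _, _ = _load_inputs(config)
    table, exclusions = build_b2g_table(et, roster, weights, config)
    if table.empty:
        raise ValueError("no eligible calves for the hutch phase")
    results = _fit_phase(table, B2G_CANDIDATES, (), config)
    tukey, paths = _emit("b2g", table, results, exclusions, config)
    logger.info("B2G: %d eligible, retained terms %s", len(table),
                results.retained)
    return PhaseOutput(table, results, tukey, exclusions, paths)


def build_g2e_table(et, roster, weights, health, milk, config
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analysis table for the group phase (one row per eligible calf)."""
    b2g_eligible, excl_b2g = filter_b2g(roster, config.max_exit_age)
    eligible, excl_g2e = filter_g2e(b2g_eligible, roster, weights, milk)
    exclusions = pd.concat([excl_b2g, excl_g2e], ignore_index=True)
    roster_idx = roster.set_index("calf_id", drop=False)
    wgt_by_calf = dict(tuple(weights.sort_values("datetime").groupby("calf_id")))
    health_by_calf = dict(tuple(health.groupby("calf_id")))
    milk_by_calf = dict(tuple(milk.groupby("calf_id")))
    rows = []
    for cid in eligible:
        row = roster_idx.loc[cid]
        birth = row["birth_datetime"]
        entry = row["hutch_exit_datetime"]
        w = wgt_by_calf[cid]
        age_days = ((w["datetime"] - birth) / pd.Timedelta(days=1)).to_numpy()
        slope = dlwg_slope(list(zip(age_days, w["weight"].to_numpy())))
        last_weigh = w["datetime"].max()
        n_days = (last_weigh.normalize() - entry.normalize()).days + 1
        cmr = avg_daily_cmr(milk_by_calf.get(cid, pd.DataFrame(
            columns=["cmr_mass"])), n_days)
        hrecs = health_by_calf.get(cid)
        statuses = []
        if hrecs is not None:
            sel = hrecs[hrecs["datetime"] >= entry]
            statuses = [classify_health(int(r), int(o)) for r, o in
                        zip(sel["rectal_score"], sel["overall_score"])]
        signs = signs_of_disease_ever(statuses) if statuses else "no"
        summary = exposure_proportion(birth, entry, last_weigh, et,
                                      config.lct_schedule,
                                      scheme=config.g2e_scheme, calf_id=cid)
        rows.append({
            "calf_id": cid, "dlwg": slope,
            "prop_cat": summary.category,
            "proportion": summary.proportion,
            "hours_below": summary.hours_below,
            "total_hours": summary.total_hours,
            "birth_weight": float(row["birth_weight"]),
            "entry_age": float(hutch_exit_age_days(birth, entry)),
            "avg_cmr": cmr, "signs_disease": signs,
            "n_weights": len(w),
            "group_id": row["group_id"], "pen_id": row["pen_id"],
            "feeder_system": row["feeder_system"],
            "treated_g2e": "yes" if row["treated_g2e"] else "no",
            **_covariates(row),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["prop_cat"] = pd.Categorical(
            table["prop_cat"], categories=list(config.g2e_scheme.labels))
    return table, exclusions


def run_g2e(config: PipelineConfig) -> PhaseOutput:
    """Group-phase analysis with crossed random intercepts."""
    _setup(config)
    _, et, roster, weights, health, milk = _load_inputs(config)
    table, exclusions = build_g2e_table(et, roster, weights, health, milk,
                                        config)
    if table.empty:
        raise ValueError("no eligible calves for the group phase")
    results = _fit_phase(table, G2E_CANDIDATES, G2E_RANDOM, config)
    tukey, paths = _emit("g2e", table, results, exclusions, config)
    logger.info("G2E: %d eligible, retained terms %s", len(table),
                results.retained)
    return PhaseOutput(table, results, tukey, exclusions, paths)


def descriptive_table(columns: dict[str, pd.Series]) -> pd.DataFrame:
    """Mean/SD/median/min/max summary, one row per named series."""
    rows = []
    for name, series in columns.items():
        s = pd.Series(series).dropna().astype(float)
        rows.append({"parameter": name, "mean": s.mean(), "sd": s.std(),
                     "median": s.median(), "min": s.min(), "max": s.max()})
    return pd.DataFrame(rows)


def report(b2g: PhaseOutput | None = None, g2e: PhaseOutput | None = None,
           climate: pd.DataFrame | None = None,
           et: pd.DataFrame | None = None, outdir: str | None = None) -> dict:
    """Descriptive summary tables computed from the phase outputs.

    Returns {'calves': frame, 'climate': frame}; optionally written as CSV
    plus a JSON round-trip of both tables.
    """
    calf_cols: dict[str, pd.Series] = {}
    if b2g is not None:
        t = b2g.table
        calf_cols["Birth weight (kg) [B2G]"] = t["birth_weight"]
        calf_cols["Age leaving individual hutch (d)"] = t["exit_age"]
        calf_cols["DLWG (kg/d) [B2G]"] = t["dlwg"]
    if g2e is not None:
        t = g2e.table
        calf_cols["Birth weight (kg) [G2E]"] = t["birth_weight"]
        calf_cols["Group pen entry age (d)"] = t["entry_age"]
        calf_cols["DLWG (kg/d) [G2E]"] = t["dlwg"]
        calf_cols["Average CMR intake (g/d)"] = t["avg_cmr"]
    climate_cols: dict[str, pd.Series] = {}
    if climate is not None:
        climate_cols["Air temperature (degC)"] = climate["air_temp"]
        climate_cols["Wind speed (m/s)"] = climate["wind_speed"]
        climate_cols["Relative humidity (%)"] = climate["rel_humidity"]
    if et is not None:
        climate_cols["Effective temperature (degC)"] = et["effective_temp"]
    if b2g is not None:
        climate_cols["Proportion hours ET < LCT (B2G)"] = b2g.table["proportion"]
    if g2e is not None:
        climate_cols["Proportion hours ET < LCT (G2E)"] = g2e.table["proportion"]

    out = {"calves": descriptive_table(calf_cols),
           "climate": descriptive_table(climate_cols)}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for name, frame in out.items():
            frame.to_csv(os.path.join(outdir, f"report_{name}.csv"),
                         index=False, float_format="%.6g")
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump({k: v.to_dict(orient="records") for k, v in out.items()},
                      fh, indent=2, default=float)
    return out
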