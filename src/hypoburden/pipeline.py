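"""End-to-end orchestration: simulate/load -> select -> expose -> estimate -> model.

Intermediate artifacts are persisted as CSV between stages so each stage can
be rerun and tested in isolation; timestamps are serialised ISO-8601 UTC and
parsed back to float hours on a common clock (the internal time axis).
Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimands, regression
from . import episodes as ep
from . import vasodose as vd
from .cohort import CohortConfig, select_cohort
from .errors import ConfigurationError, DataError, SeparationError
from .synthetic import SimConfig, simulate_cohort, ExclusionRates, MapParams, VasoParams

log = logging.getLogger(__name__)

EPOCH = pd.Timestamp("2000-01-01", tz="UTC")

TIME_COLUMNS = {
    "stays": ["icu_in", "icu_out"],
    "map_readings": ["time"],
    "infusions": ["start", "end"],
    "transfusions": ["time"],
    "deaths": ["death_time"],
    "codes": [],
    "baselines": [],
}


def hours_to_timestamp(hours) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(
        EPOCH + pd.to_timedelta(np.round(np.asarray(hours, dtype=float) * 3600.0, 3),
                                unit="s"))


def timestamp_to_hours(ts) -> np.ndarray:
    ts = pd.to_datetime(ts, utc=True, format="ISO8601")
    return ((ts - EPOCH) / pd.Timedelta(hours=1)).to_numpy()


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df = df.copy()
        for col in TIME_COLUMNS.get(name, []):
            if col in df.columns and len(df):
                df[col] = hours_to_timestamp(df[col]).strftime("%Y-%m-%dT%H:%M:%S.%fZ")
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.10g")


def read_tables(in_dir) -> dict[str, pd.DataFrame]:
    in_dir = Path(in_dir)
    tables = {}
    for name in TIME_COLUMNS:
        path = in_dir / f"{name}.csv"
        if not path.exists():
            continue
        try:
            df = pd.read_csv(path, dtype={"code": str} if name == "codes" else None)
        except pd.errors.ParserError as exc:
            raise DataError(f"malformed CSV {path.name}: {exc}") from exc
        for col in TIME_COLUMNS[name]:
            if col in df.columns and len(df):
                df[col] = timestamp_to_hours(df[col])
        tables[name] = df
    return tables


# ---------------------------------------------------------------------------
# input validation

REQUIRED_COLUMNS = {
    "stays": {"stay_id", "admission_id", "icu_in", "icu_out", "era", "age_years"},
    "map_readings": {"stay_id", "time", "map_mmhg"},
    "infusions": {"stay_id", "drug", "start", "end", "rate", "unit"},
    "transfusions": {"stay_id", "time", "volume_ml"},
    "codes": {"stay_id", "code_type", "code"},
    "baselines": {"stay_id", "age_years", "sex", "weight_kg", "sofa"},
    "deaths": {"stay_id", "death_time"},
}


def validate_inputs(tables: dict[str, pd.DataFrame]) -> list[dict]:
    """Schema, ordering and referential checks across the raw tables.

    Returns a list of findings; entries with level 'error' are hard failures
    (the pipeline refuses to run on them), 'warning' entries are downstream-
    recoverable (e.g. duplicate simultaneous readings, which are averaged).
    """
    findings: list[dict] = []

    def err(table, msg):
        findings.append({"level": "error", "table": table, "message": msg})

    def warn(table, msg):
        findings.append({"level": "warning", "table": table, "message": msg})

    for name, req in REQUIRED_COLUMNS.items():
        if name not in tables:
            err(name, "table missing")
            continue
        missing = req - set(tables[name].columns)
        if missing:
            err(name, f"missing columns: {sorted(missing)}")
    if any(f["level"] == "error" for f in findings):
        return findings

    stays = tables["stays"]
    if (stays["icu_in"] >= stays["icu_out"]).any():
        err("stays", "icu_in >= icu_out for some stays")
    if (stays["age_years"] < 0).any():
        err("stays", "negative age")
    known = set(stays["stay_id"])
    bounds = stays.set_index("stay_id")[["icu_in", "icu_out"]]

    for name, cols in (("map_readings", ("time",)), ("infusions", ("start", "end")),
                       ("transfusions", ("time",)), ("codes", ()), ("deaths", ())):
        tab = tables[name]
        orphans = set(tab["stay_id"]) - known
        if orphans:
            err(name, f"stay_id not in stays: {sorted(orphans)[:5]}")
            continue
        if len(tab) and cols:
            b = bounds.loc[tab["stay_id"]]
            for col in cols:
                t = tab[col].to_numpy()
                outside = (t < b["icu_in"].to_numpy() - 1e-6) | \
                          (t > b["icu_out"].to_numpy() + 1e-6)
                if outside.any():
                    err(name, f"{col} outside the owning stay interval "
                              f"({int(outside.sum())} events)")

    rd = tables["map_readings"]
    if len(rd) and rd.duplicated(["stay_id", "time"]).any():
        warn("map_readings", "duplicate simultaneous readings (will be averaged)")
    if len(tables["transfusions"]) and (tables["transfusions"]["volume_ml"] < 0).any():
        err("transfusions", "negative volume")
    if len(tables["infusions"]) and (tables["infusions"]["rate"] < 0).any():
        err("infusions", "negative infusion rate")
    return findings


# ---------------------------------------------------------------------------
# exposure computation

def compute_exposures(cohort: pd.DataFrame, map_readings: pd.DataFrame,
                      infusions: pd.DataFrame, baselines: pd.DataFrame,
                      support_map: dict, thresholds=ep.THRESHOLDS_MMHG,
                      max_gap_hours: float = 1.5,
                      lookback_hours: float = 1.0) -> pd.DataFrame:
    """Per-stay burden summary table: one column block per threshold plus
    baseline MAP and maximum NED."""
    rd_map = {sid: g for sid, g in map_readings.groupby("stay_id", sort=False)}
    inf_map = {sid: g for sid, g in infusions.groupby("stay_id", sort=False)}
    weights = baselines.set_index("stay_id")["weight_kg"]
    rows = []
    for sid in cohort["stay_id"]:
        support = support_map.get(sid, [])
        g = rd_map.get(sid)
        times = g["time"].to_numpy() if g is not None else np.empty(0)
        values = g["map_mmhg"].to_numpy() if g is not None else np.empty(0)
        summary = ep.summarize_stay(sid, times, values, support,
                                    thresholds=thresholds,
                                    max_gap_hours=max_gap_hours,
                                    vasopressor_start=support[0][0] if support else None,
                                    lookback_hours=lookback_hours)
        row = {"stay_id": sid,
               "baseline_map_mmhg": (np.nan if summary.baseline_map_mmhg is None
                                     else summary.baseline_map_mmhg),
               "support_hours": summary.total_support_hours}
        for thr in thresholds:
            rec = summary.per_threshold[thr]
            row[f"ever_{int(thr)}"] = rec["ever"]
            row[f"longest_{int(thr)}"] = rec["longest"]
            row[f"cumulative_{int(thr)}"] = rec["cumulative"]
        gi = inf_map.get(sid)
        if gi is not None and len(gi):
            recs = [vd.InfusionRecord(r.stay_id, r.drug, r.start, r.end, r.rate, r.unit)
                    for r in gi.itertuples()]
            series = vd.ned_step_function(recs, weight_kg=weights.get(sid, np.nan),
                                          stay_id=sid)
            row["max_ned"], _ = vd.max_ned(series)
            row["high_dose"] = vd.high_dose_flag(series)
        else:
            row["max_ned"], row["high_dose"] = 0.0, False
        rows.append(row)
    return pd.DataFrame(rows)


def attribute_outcomes(cohort: pd.DataFrame, deaths: pd.DataFrame) -> pd.DataFrame:
    """ICU-death (within 24 h of discharge) and 28-day death per cohort stay."""
    from .cohort import icu_death
    dmap = deaths.set_index("stay_id")["death_time"]
    rows = []
    for r in cohort.itertuples():
        dt = dmap.get(r.stay_id, np.nan)
        dead_icu = icu_death(None if pd.isna(dt) else float(dt),
                             float(r.icu_out), float(r.icu_in))
        day28 = bool(not pd.isna(dt) and dt <= r.icu_in + 672.0 + 1e-9)
        rows.append({"stay_id": r.stay_id, "icu_death": dead_icu,
                     "death_time": dt, "day28_death": day28})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run config and the full pipeline

@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    simulate: SimConfig | None = None
    input_dir: str | None = None
    thresholds: tuple[float, ...] = ep.THRESHOLDS_MMHG
    scheme: str = "2h"
    max_gap_hours: float = 1.5
    gap_tolerance_minutes: float = 15.0
    alpha: float = 0.05
    run_sensitivity: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        if not self.thresholds or list(self.thresholds) != sorted(self.thresholds):
            raise ConfigurationError("thresholds must be nonempty and sorted")
        if self.simulate is None and self.input_dir is None:
            raise ConfigurationError("either a simulate block or input_dir is required")
        if self.simulate is None and not Path(self.input_dir).exists():
            raise ConfigurationError(f"input_dir does not exist: {self.input_dir}")


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML/JSON key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "cohort"})
    if "cohort" in raw:
        cfg.cohort = CohortConfig(**raw["cohort"])
    if sim is not None:
        for key, cls in (("map", MapParams), ("vaso", VasoParams),
                         ("exclusions", ExclusionRates)):
            if key in sim:
                sim[key] = cls(**sim[key])
        cfg.simulate = SimConfig(**sim)
    if isinstance(cfg.thresholds, list):
        cfg.thresholds = tuple(cfg.thresholds)
    return cfg


def _config_hash(config: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    blob = json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all result tables under config.out_dir.

    Returns the in-memory result bundle (tables, cohort, ledger, exposures,
    estimands, model fits). Any stage error propagates with its stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- stage: data
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        tables, truth = simulate_cohort(sim)
        write_tables(tables, out / "tables")
        truth.to_csv(out / "tables" / "sim_truth.csv", index=False, float_format="%.10g")
        bundle["truth"] = truth
    else:
        tables = read_tables(config.input_dir)
    bundle["tables"] = tables

    # --- stage: validation
    findings = validate_inputs(tables)
    pd.DataFrame(findings, columns=["level", "table", "message"]).to_csv(
        out / "validation.csv", index=False)
    hard = [f for f in findings if f["level"] == "error"]
    if hard:
        raise DataError(f"stage validate_inputs: {hard[0]['table']}: {hard[0]['message']}")

    # --- stage: cohort selection
    cohort_df, ledger, support_map = select_cohort(
        tables["stays"], tables["infusions"], tables["map_readings"],
        tables["transfusions"], tables["codes"], config.cohort)
    _write_csv(ledger.to_frame(), out / "exclusion_ledger.csv", index=False)
    (out / "cohort_flowchart.txt").write_text(ledger.flowchart() + "\n")
    bundle["cohort"], bundle["ledger"] = cohort_df, ledger
    if len(cohort_df) == 0:
        log.warning("empty cohort; downstream stages skipped")
        return bundle

    # --- stage: exposures and outcomes
    exposures = compute_exposures(cohort_df, tables["map_readings"],
                                  tables["infusions"], tables["baselines"],
                                  support_map, config.thresholds,
                                  config.max_gap_hours)
    outcomes = attribute_outcomes(cohort_df, tables["deaths"])
    _write_csv(exposures, out / "exposures.csv", index=False)
    _write_csv(outcomes, out / "outcomes.csv", index=False)
    bundle["exposures"], bundle["outcomes"] = exposures, outcomes

    # --- stage: descriptive estimands
    era = cohort_df.set_index("stay_id")["era"].loc[exposures["stay_id"]]
    strata = estimands.stratify_era(exposures, era.reset_index(drop=True),
                                    config.thresholds)
    for name, tab in strata.items():
        if tab is not None:
            _write_csv(tab, out / f"prevalence_{name}.csv")
    y = outcomes.set_index("stay_id")["icu_death"].loc[exposures["stay_id"]]
    slopes = {}
    for thr in config.thresholds:
        bm = estimands.mortality_by_bin(exposures, y.reset_index(drop=True),
                                        thr, config.scheme, config.alpha)
        _write_csv(bm, out / f"mortality_by_bin_{int(thr)}.csv")
        bundle[f"mortality_by_bin_{int(thr)}"] = bm
        try:
            slopes[thr] = estimands.trend_slope(bm, config.scheme)
        except Exception as exc:  # undefined trend on degenerate strata
            log.warning("trend slope at %s: %s", thr, exc)
            slopes[thr] = np.nan
    _write_csv(pd.Series(slopes, name="pp_per_2h").rename_axis("threshold").to_frame(),
               out / "trend_slopes.csv")
    bundle["prevalence"], bundle["trend_slopes"] = strata, slopes

    # --- stage: regression
    baselines = tables["baselines"]
    cov = regression.encode_covariates(baselines, exposures, 65.0, config.scheme)
    yv = outcomes.set_index("stay_id")["icu_death"].loc[cov.index].to_numpy(dtype=bool)
    try:
        fit = regression.fit_primary_model(cov, yv, scheme=config.scheme)
    except (SeparationError, DataError) as exc:
        # small cohorts can present all-death / all-survivor cells; the model
        # is reported as unavailable rather than with meaningless estimates
        log.warning("primary model: %s", exc)
        fit = None
    bundle["fit_primary"] = fit
    _write_csv(fit.table if fit is not None
               else pd.DataFrame(columns=["estimate", "se", "wald_chi2", "p", "odds_ratio"]),
               out / "model_primary.csv")
    sweep = regression.threshold_sweep(baselines, exposures, yv,
                                       [t for t in config.thresholds if t != 65.0],
                                       config.scheme)
    _write_csv(regression.sweep_table(sweep, config.scheme), out / "model_threshold_sweep.csv")
    bundle["fit_sweep"] = sweep
    if fit is not None:
        marg = pd.concat([regression.marginal_mortality(fit, cov, "duration"),
                          regression.marginal_mortality(fit, cov, "dose")],
                         keys=["duration", "dose"])
        bundle["marginals"] = marg
    else:
        marg = pd.Series(dtype=float)
    _write_csv(marg.to_frame("predicted_mortality"), out / "marginal_mortality.csv")

    # --- stage: sensitivity suite
    if config.run_sensitivity:
        sens = regression.sensitivity_suite(baselines, exposures, outcomes, cohort_df)
        _write_csv(regression.sensitivity_table(sens), out / "sensitivity_or_table.csv")
        bundle["sensitivity"] = sens

    meta = {"config_hash": _config_hash(config), "seed": config.seed,
            "n_raw": int(len(tables["stays"])), "n_cohort": int(len(cohort_df))}
    (out / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    bundle["meta"] = meta
    return bundle
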