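"""Synthetic MIMIC-like ICU cohort generator with planted ground truth.

Stands in for the access-controlled source data so the whole pipeline is
testable end to end. Per stay it generates:

* a latent minute-resolution MAP path — AR(1) around a per-stay baseline,
  with planted "dip" segments (additive negative excursions during
  vasopressor support) so true episode durations are known exactly;
* irregular point readings of that path (jittered ~hourly spacing, optional
  artefact values, optional planted charting gaps);
* vasopressor infusion records (multi-drug, multi-unit, piecewise rates,
  occasional sub-tolerance record splits);
* exclusion-triggering records (diagnosis/procedure/DRG codes, massive
  transfusion clusters, under-age stays, duplicate qualifying stays) at
  configured independent rates;
* baseline covariates with cohort-realistic marginals, and an ICU-death outcome
  drawn from a planted logistic model on the *recovered* duration bin (the
  bin the episodes module computes from the sampled readings) plus
  covariates, so downstream model fitting is estimating exactly the planted
  coefficients.

A separate design-level sampler (`simulate_regression_replicate`) draws
duration bins, covariates and outcomes directly from the planted logistic
model without the waveform layer; it powers the replicated
parameter-recovery experiment at large n.

All tables use float hours on a common clock internally (the io layer
serialises ISO-8601); one RNG stream per table is split from the master
seed, so adding a table never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, special

from . import episodes as ep
from . import vasodose as vd
from .cohort import CohortConfig, stay_support_intervals
from .errors import ConfigurationError
from .intervals import point_in_intervals
from .regression import DesignSpec, primary_design_spec

EPOCH_2001 = 8760.0          # hours since 2000-01-01 at 2001-01-01
EPOCH_MID2008 = 74544.0      # ~2008-07-01
EPOCH_MID2012 = 109572.0     # ~2012-06-30

#: Planted log-odds of the full generator's outcome model (reference
#: categories carry 0 implicitly). These defaults reproduce the adjusted
#: model scale of a large distributive-shock cohort.
DEFAULT_OUTCOME_COEFFICIENTS = {
    "intercept": -3.39,
    "baseline_map": {"<65": 0.15, "missing": -0.36},
    "duration": {">0 to <2": 0.57, ">=2 to <4": 0.66, ">=4 to <6": 0.80,
                 ">=6 to <8": 1.06, ">=8 to <10": 1.24, ">=10 to <12": 1.47,
                 ">=12 to <16": 1.67, ">=16 to <20": 1.70, ">=20": 1.96},
    "dose": {">=0.2 to <0.5": 0.64, ">=0.5 to <1.0": 1.44, ">=1.0 to <1.5": 1.85,
             ">=1.5 to <2.0": 2.07, ">=2.0 to <2.5": 2.08, ">=2.5": 1.61},
    "age": {"65-74": 0.33, "75-84": 0.48, ">=85": 0.73},
    "sex": {"female": -0.07},
    "sepsis": {"yes": -0.19},
    "sofa": {">4 to <=6": 0.03, ">6 to <=8": 0.09, ">8 to <=10": 0.32, ">10": 1.09},
    "hypertension": {"yes": -0.02},
    "ventilated": {"yes": 0.15},
    "rrt": {"yes": 1.26},
    "albumin": {"<2.5": 0.60, "missing": 0.18},
    "creatinine": {">=2.0": -0.09, "missing": -0.55},
    "lactate": {">=2.0": 0.38, "missing": 0.37},
}


@dataclass
class MapParams:
    mean_range: tuple[float, float] = (70.0, 88.0)   # per-stay baseline, mmHg
    ar1_phi: float = 0.97                            # per-minute autocorrelation
    noise_sd: float = 2.0                            # innovation SD, mmHg
    sampling_interval_mean: float = 47.5             # minutes between readings
    sampling_interval_jitter: float = 12.0           # SD of the gap, minutes
    sampling_interval_bounds: tuple[float, float] = (15.0, 90.0)
    artifact_rate: float = 0.002                     # implausible charted values
    dip_prob: float = 0.70                           # P(stay has >=1 planted dip)
    dip_depth_range: tuple[float, float] = (10.0, 35.0)   # mmHg below baseline
    dip_duration_median: float = 3.0                 # hours (lognormal)
    dip_duration_sigma: float = 1.1
    dip_extra_mean: float = 1.5                      # extra dips ~ Poisson


@dataclass
class VasoParams:
    short_support_rate: float = 0.04   # stays whose support never reaches 6 h
    second_drug_prob: float = 0.35
    rate_median: float = 0.12          # µg/kg/min norepinephrine (lognormal)
    rate_sigma: float = 1.0
    split_record_prob: float = 0.2     # split one record by a sub-tolerance gap


@dataclass
class ExclusionRates:
    underage: float = 0.010
    cardiogenic_shock: float = 0.010
    cardiac_tamponade: float = 0.002
    pulmonary_embolus: float = 0.004
    iabp_ecmo: float = 0.004
    excluded_drg: float = 0.010
    rbc_massive: float = 0.010
    data_gap: float = 0.010
    duplicate_stay: float = 0.010


@dataclass
class SimConfig:
    n_stays: int = 1000
    seed: int = 0
    los_median_hours: float = 84.0
    los_sigma: float = 0.6
    los_bounds: tuple[float, float] = (12.0, 500.0)
    map: MapParams = field(default_factory=MapParams)
    vaso: VasoParams = field(default_factory=VasoParams)
    exclusions: ExclusionRates = field(default_factory=ExclusionRates)
    outcome_coefficients: dict = field(default_factory=lambda: DEFAULT_OUTCOME_COEFFICIENTS)
    late_death_prob: float = 0.10      # ICU survivors dying before day 28
    max_gap_hours: float = 1.5         # carry-forward cap used to recover exposure
    # optional severity gradient: extra log-odds of death per hour of the
    # longest episode below `severity_threshold` (capped). Off by default so
    # the categorical ladder is the exact generating model; turned on to
    # plant steeper mortality-duration slopes at deeper thresholds.
    severity_coef_per_hour: float = 0.0
    severity_threshold: float = 55.0
    severity_cap_hours: float = 24.0

    def validate(self) -> None:
        if self.n_stays < 0:
            raise ConfigurationError("n_stays must be nonnegative")
        if not 0.0 < self.map.ar1_phi < 1.0:
            raise ConfigurationError("map.ar1_phi must lie in (0, 1)")
        if self.map.noise_sd < 0:
            raise ConfigurationError("map.noise_sd must be nonnegative")
        if self.map.sampling_interval_mean <= 0:
            raise ConfigurationError("map.sampling_interval_mean must be positive")
        if self.los_median_hours <= 0 or self.los_sigma <= 0:
            raise ConfigurationError("los parameters must be positive")
        for f in dataclasses.fields(ExclusionRates):
            v = getattr(self.exclusions, f.name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"exclusion rate {f.name} outside [0, 1]")
        if not 0.0 <= self.late_death_prob <= 1.0:
            raise ConfigurationError("late_death_prob outside [0, 1]")
        if "intercept" not in self.outcome_coefficients:
            raise ConfigurationError("outcome_coefficients needs an intercept")


# ---------------------------------------------------------------------------
# latent MAP path and readings

def simulate_latent_path(n_minutes: int, baseline: float, params: MapParams,
                         rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path on a 1-minute grid around the stay baseline."""
    eps = rng.normal(0.0, params.noise_sd, size=n_minutes)
    stat_sd = params.noise_sd / np.sqrt(1.0 - params.ar1_phi ** 2)
    x0 = rng.normal(0.0, stat_sd)
    path, _ = signal.lfilter([1.0], [1.0, -params.ar1_phi], eps,
                             zi=np.array([params.ar1_phi * x0]))
    return baseline + path


def plant_dips(path: np.ndarray, support_minutes: np.ndarray, params: MapParams,
               rng: np.random.Generator) -> np.ndarray:
    """Subtract planted hypotension dips inside vasopressor support."""
    idx = np.flatnonzero(support_minutes)
    if len(idx) == 0 or rng.random() >= params.dip_prob:
        return path
    n_dips = 1 + rng.poisson(params.dip_extra_mean)
    out = path.copy()
    for _ in range(n_dips):
        dur_h = np.exp(rng.normal(np.log(params.dip_duration_median),
                                  params.dip_duration_sigma))
        dur = int(np.clip(dur_h * 60, 30, 30 * 60))
        start = int(rng.choice(idx))
        depth = rng.uniform(*params.dip_depth_range)
        lo, hi = start, min(start + dur, len(out))
        # soft edges so the excursion is not a square wave
        ramp = min(15, max(1, (hi - lo) // 4))
        shape = np.ones(hi - lo)
        shape[:ramp] = np.linspace(0.3, 1.0, ramp)
        shape[-ramp:] = np.linspace(1.0, 0.3, ramp)
        out[lo:hi] -= depth * shape
    return out


def sample_reading_times(n_minutes: int, params: MapParams,
                         rng: np.random.Generator) -> np.ndarray:
    """Integer reading minutes with jittered spacing across the stay."""
    t = float(rng.uniform(0, 20))
    times = []
    while t < n_minutes - 1:
        times.append(int(round(t)))
        g = rng.normal(params.sampling_interval_mean, params.sampling_interval_jitter)
        t += float(np.clip(g, *params.sampling_interval_bounds))
    return np.unique(np.asarray(times, dtype=int))


def simulate_map_series(icu_in: float, icu_out: float, params: MapParams,
                        rng: np.random.Generator,
                        support: list[tuple[float, float]] | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One stay's MAP readings: (times in hours, charted values, latent path).

    The latent path is returned so callers can derive exact ground truth;
    charted values are point samples of it, with a small artefact rate
    replaced by implausible values (to exercise downstream cleaning).
    """
    if icu_out <= icu_in:
        raise ConfigurationError("stay interval is empty")
    if params.sampling_interval_mean <= 0:
        raise ConfigurationError("sampling interval must be positive")
    n_minutes = max(2, int(round((icu_out - icu_in) * 60)))
    baseline = rng.uniform(*params.mean_range)
    path = simulate_latent_path(n_minutes, baseline, params, rng)
    if support:
        minute_t = icu_in + (np.arange(n_minutes) + 0.5) / 60.0
        path = plant_dips(path, point_in_intervals(minute_t, support), params, rng)
    minutes = sample_reading_times(n_minutes, params, rng)
    times = icu_in + minutes / 60.0
    values = path[minutes].copy()
    art = rng.random(len(values)) < params.artifact_rate
    values[art] = rng.choice([4.0, 300.0], size=int(art.sum()))
    return times, values, path


def latent_longest_below(path: np.ndarray, icu_in: float,
                         support: list[tuple[float, float]],
                         threshold: float) -> float:
    """Exact longest below-threshold run (hours) of the minute-grid path
    restricted to support — the planted ground truth."""
    n = len(path)
    minute_t = icu_in + (np.arange(n) + 0.5) / 60.0
    mask = (path < threshold) & point_in_intervals(minute_t, support)
    if not mask.any():
        return 0.0
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    runs = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
    return float(runs.max()) / 60.0


# ---------------------------------------------------------------------------
# outcome model

def _linear_predictor(categories: dict[str, str], coefficients: dict,
                      spec: DesignSpec) -> float:
    lp = float(coefficients["intercept"])
    for term, (cats, ref) in spec.terms.items():
        cat = categories[term]
        if cat == ref:
            continue
        term_coefs = coefficients.get(term, {})
        if cat not in term_coefs:
            raise ConfigurationError(
                f"no outcome coefficient for {term}={cat!r} present in data")
        lp += float(term_coefs[cat])
    return lp


def assign_outcome(categories: dict[str, str], coefficients: dict,
                   rng: np.random.Generator, icu_in: float, icu_out: float,
                   late_death_prob: float = 0.10,
                   spec: DesignSpec | None = None,
                   lp_offset: float = 0.0) -> dict:
    """Draw the death indicator and timestamps from the planted logistic model.

    ICU deaths are stamped within 24 h after ICU discharge so the outcome
    rule recovers them exactly; a fraction of ICU survivors receive a later
    death for the 28-day sensitivity outcome.
    """
    spec = spec or primary_design_spec()
    lp = _linear_predictor(categories, coefficients, spec) + lp_offset
    p = float(special.expit(lp))
    icu_death = bool(rng.random() < p)
    death_time = np.nan
    if icu_death:
        death_time = icu_out + float(rng.uniform(0.0, 24.0))
    elif rng.random() < late_death_prob:
        death_time = icu_out + 24.0 + float(rng.uniform(0.0, 500.0))
    day28 = bool(np.isfinite(death_time) and death_time <= icu_in + 672.0)
    return {"death_prob": p, "icu_death": icu_death,
            "death_time": death_time, "day28_death": day28}


# ---------------------------------------------------------------------------
# covariates (cohort-realistic marginals)

def draw_covariates(rng: np.random.Generator) -> dict:
    age = float(np.clip(rng.normal(66.3, 15.7), 18.0, 100.0))
    weight = float(np.clip(rng.normal(81.6, 25.2), 35.0, 220.0))
    if rng.random() < 0.011:
        weight = np.nan
    lab = lambda mu, sd, lo, hi, miss: (np.nan if rng.random() < miss
                                        else float(np.clip(rng.normal(mu, sd), lo, hi)))
    return {
        "age_years": age,
        "sex": "female" if rng.random() < 0.466 else "male",
        "weight_kg": weight,
        "sofa": int(np.clip(round(rng.normal(7.4, 3.8)), 0, 24)),
        "sepsis": rng.random() < 0.704,
        "hypertension": rng.random() < 0.324,
        "ventilated": rng.random() < 0.513,
        "rrt": rng.random() < 0.007,
        "lactate": lab(3.0, 2.6, 0.3, 20.0, 0.256),
        "albumin": lab(2.9, 0.7, 1.0, 5.5, 0.584),
        "creatinine": lab(2.0, 1.9, 0.2, 15.0, 0.055),
    }


# ---------------------------------------------------------------------------
# infusions

def simulate_infusions(stay_id, icu_in: float, icu_out: float, weight_kg: float,
                       params: VasoParams, rng: np.random.Generator) -> list[dict]:
    """Vasopressor records for one stay: norepinephrine backbone with
    piecewise rates, optional second agent, occasional sub-tolerance split."""
    los = icu_out - icu_in
    if rng.random() < params.short_support_rate:
        dur = float(rng.uniform(1.0, 5.0))
    else:
        dur = float(rng.uniform(6.0, max(6.5, 0.9 * los)))
    dur = min(dur, los - 0.5)
    start = icu_in + float(rng.uniform(0.0, max(0.1, los - dur - 0.2)))
    end = start + dur
    records = []
    # norepinephrine backbone, 1-4 rate segments
    n_seg = int(rng.integers(1, 5))
    cuts = np.sort(rng.uniform(start, end, size=n_seg - 1))
    bounds = np.concatenate([[start], cuts, [end]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 1e-3:
            continue
        rate = float(np.exp(rng.normal(np.log(params.rate_median), params.rate_sigma)))
        records.append(dict(stay_id=stay_id, drug="norepinephrine",
                            start=float(a), end=float(b),
                            rate=round(rate, 4), unit="ug/kg/min"))
    if rng.random() < params.second_drug_prob:
        u = rng.random()
        a = start + float(rng.uniform(0.0, 0.5 * dur))
        b = min(end, a + float(rng.uniform(0.2, 0.8) * dur))
        if b - a > 0.1:
            if u < 0.5:
                records.append(dict(stay_id=stay_id, drug="vasopressin",
                                    start=a, end=b,
                                    rate=round(float(rng.uniform(0.01, 0.04)), 4),
                                    unit="U/min"))
            elif u < 0.75 and np.isfinite(weight_kg):
                # phenylephrine charted in µg/min (total-dose units)
                per_kg = float(np.exp(rng.normal(np.log(0.5), 0.5)))
                records.append(dict(stay_id=stay_id, drug="phenylephrine",
                                    start=a, end=b,
                                    rate=round(per_kg * weight_kg, 2), unit="ug/min"))
            else:
                records.append(dict(stay_id=stay_id, drug="dopamine",
                                    start=a, end=b,
                                    rate=round(float(rng.uniform(2.0, 10.0)), 3),
                                    unit="ug/kg/min"))
    if records and rng.random() < params.split_record_prob:
        # split the first record by a gap inside the merge tolerance
        r = records[0]
        mid = 0.5 * (r["start"] + r["end"])
        gap = float(rng.uniform(2.0, 12.0)) / 60.0
        if mid + gap < r["end"] - 0.05:
            r2 = dict(r)
            r["end"] = mid
            r2["start"] = mid + gap
            records.insert(1, r2)
    return records


# ---------------------------------------------------------------------------
# full cohort

TABLE_NAMES = ("stays", "map_readings", "infusions", "transfusions",
               "codes", "baselines", "deaths")

_EXCL_CODE = {
    "cardiogenic_shock": ("diagnosis", "78551"),
    "cardiac_tamponade": ("diagnosis", "4233"),
    "pulmonary_embolus": ("diagnosis", "4151"),
    "iabp_ecmo": ("procedure", "3761"),
    "excluded_drg": ("drg", "104"),
}


def _empty_tables() -> dict[str, pd.DataFrame]:
    cols = {
        "stays": ["stay_id", "admission_id", "icu_in", "icu_out", "era", "age_years"],
        "map_readings": ["stay_id", "time", "map_mmhg"],
        "infusions": ["stay_id", "drug", "start", "end", "rate", "unit"],
        "transfusions": ["stay_id", "time", "volume_ml"],
        "codes": ["stay_id", "code_type", "code"],
        "baselines": ["stay_id", "age_years", "sex", "weight_kg", "sofa", "sepsis",
                      "hypertension", "ventilated", "rrt", "lactate", "albumin",
                      "creatinine"],
        "deaths": ["stay_id", "death_time"],
    }
    return {k: pd.DataFrame(columns=v) for k, v in cols.items()}


def simulate_cohort(config: SimConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate all raw tables plus the SimTruth frame.

    Deterministic in ``config.seed``: one spawned RNG stream per concern,
    stays iterated in fixed order.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(ss) for name, ss in
               zip(("stays", "infusions", "map", "transfusions", "codes",
                    "baselines", "outcome"),
                   master.spawn(7))}
    n = config.n_stays
    tables = _empty_tables()
    if n == 0:
        return tables, pd.DataFrame()

    rs = streams["stays"]
    icu_in = rs.uniform(EPOCH_2001, EPOCH_MID2012, size=n)
    los = np.exp(rs.normal(np.log(config.los_median_hours), config.los_sigma, size=n))
    los = np.clip(los, *config.los_bounds)
    icu_out = icu_in + los
    era = np.where(icu_in < EPOCH_MID2008, "pre2008", "post2008")
    admission = np.arange(n)
    dup = rs.random(n) < config.exclusions.duplicate_stay
    dup[0] = False
    admission[dup] = admission[np.flatnonzero(dup) - 1]

    rb = streams["baselines"]
    covs = [draw_covariates(rb) for _ in range(n)]
    underage = rb.random(n) < config.exclusions.underage
    for i in np.flatnonzero(underage):
        covs[i]["age_years"] = float(rb.uniform(16.0, 17.9))

    ri = streams["infusions"]
    stay_infusions: dict[int, list[dict]] = {}
    infusion_rows: list[dict] = []
    for i in range(n):
        recs = simulate_infusions(i, icu_in[i], icu_out[i],
                                  covs[i]["weight_kg"], config.vaso, ri)
        stay_infusions[i] = recs
        infusion_rows += recs
    infusions = pd.DataFrame(infusion_rows)

    support_map = stay_support_intervals(infusions, CohortConfig())

    rm = streams["map"]
    reading_rows = []
    truth_rows = []
    spec = primary_design_spec()
    ro = streams["outcome"]
    gap_planted = rm.random(n) < config.exclusions.data_gap
    for i in range(n):
        support = support_map.get(i, [])
        times, values, path = simulate_map_series(icu_in[i], icu_out[i],
                                                  config.map, rm, support)
        if gap_planted[i] and len(times) > 4:
            g0 = icu_in[i] + float(rm.uniform(0.1, 0.4)) * los[i]
            g1 = g0 + float(rm.uniform(26.0, 34.0))
            keep = (times < g0) | (times > g1)
            times, values = times[keep], values[keep]
        for t, v in zip(times, values):
            reading_rows.append((i, float(t), float(round(v, 1))))

        truth = {"stay_id": i}
        for thr in ep.THRESHOLDS_MMHG:
            truth[f"true_longest_{int(thr)}"] = latent_longest_below(
                path, icu_in[i], support, thr)

        # exposure as the pipeline will see it, for the outcome model
        summary = ep.summarize_stay(i, times, values, support,
                                    max_gap_hours=config.max_gap_hours,
                                    vasopressor_start=support[0][0] if support else None)
        rec65 = summary.per_threshold[65.0]
        stay_inf = [vd.InfusionRecord(**{k: r[k] for k in
                                         ("stay_id", "drug", "start", "end", "rate", "unit")})
                    for r in stay_infusions[i]]
        series = vd.ned_step_function(stay_inf, weight_kg=covs[i]["weight_kg"], stay_id=i)
        peak, dbin = vd.max_ned(series)
        cats = {
            "baseline_map": ("missing" if summary.baseline_map_mmhg is None
                             else ("<65" if summary.baseline_map_mmhg < 65 else ">=65")),
            "duration": ep.duration_bin(rec65["longest"], rec65["ever"], "2h"),
            "dose": dbin,
            "age": _age_cat(covs[i]["age_years"]),
            "sex": covs[i]["sex"],
            "sepsis": "yes" if covs[i]["sepsis"] else "no",
            "sofa": _sofa_cat(covs[i]["sofa"]),
            "hypertension": "yes" if covs[i]["hypertension"] else "no",
            "ventilated": "yes" if covs[i]["ventilated"] else "no",
            "rrt": "yes" if covs[i]["rrt"] else "no",
            "albumin": _lab_cat(covs[i]["albumin"], 2.5, False),
            "creatinine": _lab_cat(covs[i]["creatinine"], 2.0, True),
            "lactate": _lab_cat(covs[i]["lactate"], 2.0, True),
        }
        sev = 0.0
        if config.severity_coef_per_hour:
            sev_long = summary.per_threshold[config.severity_threshold]["longest"]
            sev = config.severity_coef_per_hour * min(sev_long, config.severity_cap_hours)
        outcome = assign_outcome(cats, config.outcome_coefficients, ro,
                                 icu_in[i], icu_out[i], config.late_death_prob, spec,
                                 lp_offset=sev)
        truth.update({"duration_bin_65": cats["duration"], "dose_bin": dbin,
                      "max_ned": peak, "death_prob": outcome["death_prob"],
                      "icu_death": outcome["icu_death"],
                      "day28_death": outcome["day28_death"],
                      "death_time": outcome["death_time"],
                      "planted_gap": bool(gap_planted[i]),
                      "planted_underage": bool(underage[i])})
        truth_rows.append(truth)

    rt = streams["transfusions"]
    tx_rows = []
    massive = rt.random(n) < config.exclusions.rbc_massive
    for i in range(n):
        if massive[i]:
            span = min(24.0, max(2.0, los[i] - 1.0))
            t0 = icu_in[i] + float(rt.uniform(0.0, max(0.1, los[i] - span - 0.5)))
            total = float(rt.uniform(3600.0, 5200.0))
            parts = rt.dirichlet(np.ones(3)) * total
            offs = np.sort(rt.uniform(0.0, span, size=3))
            for o, v in zip(offs, parts):
                tx_rows.append((i, min(t0 + float(o), icu_out[i] - 0.1),
                                float(round(v, 0))))
        elif rt.random() < 0.10:
            tx_rows.append((i, icu_in[i] + float(rt.uniform(0.0, los[i])),
                            float(round(rt.uniform(200.0, 900.0), 0))))

    rc = streams["codes"]
    code_rows = []
    for i in range(n):
        # benign background codes
        code_rows.append((i, "diagnosis", "0389"))
        if rc.random() < 0.5:
            code_rows.append((i, "drg", "870"))
        for rule, (ctype, code) in _EXCL_CODE.items():
            if rc.random() < getattr(config.exclusions, rule):
                code_rows.append((i, ctype, code))

    truth = pd.DataFrame(truth_rows)
    tables["stays"] = pd.DataFrame({
        "stay_id": np.arange(n), "admission_id": admission,
        "icu_in": icu_in, "icu_out": icu_out, "era": era,
        "age_years": [c["age_years"] for c in covs]})
    tables["map_readings"] = pd.DataFrame(reading_rows,
                                          columns=["stay_id", "time", "map_mmhg"])
    tables["infusions"] = infusions
    tables["transfusions"] = pd.DataFrame(tx_rows,
                                          columns=["stay_id", "time", "volume_ml"])
    tables["codes"] = pd.DataFrame(code_rows, columns=["stay_id", "code_type", "code"])
    tables["baselines"] = pd.DataFrame(
        [{"stay_id": i, **covs[i]} for i in range(n)])
    dead = truth[np.isfinite(truth["death_time"])]
    tables["deaths"] = pd.DataFrame({"stay_id": dead["stay_id"],
                                     "death_time": dead["death_time"]})
    return tables, truth


def _age_cat(a):
    from .regression import age_category
    return age_category(a)


def _sofa_cat(s):
    from .regression import sofa_category
    return sofa_category(s)


def _lab_cat(v, cut, high_is_flagged):
    from .regression import _lab_category
    return _lab_category(v, cut, high_is_flagged)


# ---------------------------------------------------------------------------
# design-level replicate sampler for the parameter-recovery experiment

#: Evenly spaced, strictly increasing duration-bin log-odds spanning the
#: adjusted-model scale (0.57 for the shortest exposed bin up to 1.96 for
#: >=20 h). Even spacing maximises the minimum adjacent gap, which is what
#: makes the planted *ordering* recoverable at the experiment's sample size.
RECOVERY_LADDER = dict(zip(ep.BIN_LABELS_2H, np.round(np.linspace(0.57, 1.96, 9), 5)))
#: Centres the exposed bins' death probabilities on 1/2 (where the Fisher
#: information per subject peaks): minus the mid-ladder coefficient (1.265)
#: and minus the mean covariate contribution (~0.235 at the prevalences below).
RECOVERY_INTERCEPT = -1.50
RECOVERY_COVARIATES = {
    # term -> (prevalence of the non-reference category, log-odds)
    "sex": (0.466, -0.07),
    "ventilated": (0.513, 0.15),
    "lactate": (0.5, 0.38),
}
#: Bin allocation: 10% never-below, the rest equally across exposed bins.
RECOVERY_NEVER_FRAC = 0.10


def recovery_design_spec() -> DesignSpec:
    return DesignSpec(terms={
        "duration": ((ep.NEVER_BELOW,) + ep.BIN_LABELS_2H, ep.NEVER_BELOW),
        "sex": (("male", "female"), "male"),
        "ventilated": (("no", "yes"), "no"),
        "lactate": (("<2.0", ">=2.0"), "<2.0"),
    })


def simulate_regression_replicate(n_stays: int, rng: np.random.Generator,
                                  ladder: dict[str, float] | None = None,
                                  intercept: float = RECOVERY_INTERCEPT
                                  ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw (covariates, outcome, death probabilities) from the planted model.

    Skips the waveform layer entirely: duration bins are drawn from the
    allocation above, covariates from their prevalences, outcomes Bernoulli
    from the planted logistic model. Returns (cov frame, y, p).
    """
    ladder = RECOVERY_LADDER if ladder is None else ladder
    labels = [ep.NEVER_BELOW] + list(ep.BIN_LABELS_2H)
    k = len(ep.BIN_LABELS_2H)
    probs = np.array([RECOVERY_NEVER_FRAC] + [(1 - RECOVERY_NEVER_FRAC) / k] * k)
    bins = rng.choice(len(labels), size=n_stays, p=probs)
    cov = pd.DataFrame({"duration": np.array(labels, dtype=object)[bins]})
    lp = np.full(n_stays, intercept)
    for lab, coef in ladder.items():
        lp += np.where(cov["duration"] == lab, coef, 0.0)
    for term, (prev, coef) in RECOVERY_COVARIATES.items():
        flag = rng.random(n_stays) < prev
        if term == "sex":
            cov[term] = np.where(flag, "female", "male")
        elif term == "lactate":
            cov[term] = np.where(flag, ">=2.0", "<2.0")
        else:
            cov[term] = np.where(flag, "yes", "no")
        lp += np.where(flag, coef, 0.0)
    p = special.expit(lp)
    y = rng.random(n_stays) < p
    return cov, y, p


def recovery_experiment(n_replicates: int = 100, n_stays: int = 20_000,
                        seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Replicated coverage/ordering experiment for the planted duration ladder.

    Each replicate draws a fresh cohort from `simulate_regression_replicate`,
    fits the reduced logistic model, and records per-bin estimates, SEs,
    whether the Wald CI covers the planted value, and whether the fitted
    odds ratios are monotone nondecreasing in duration.
    """
    from scipy.stats import norm
    from .regression import fit_logistic
    z = norm.ppf(1 - alpha / 2)
    spec = recovery_design_spec()
    rows = []
    rng_master = np.random.SeedSequence(seed)
    for rep, ss in enumerate(rng_master.spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        cov, y, _ = simulate_regression_replicate(n_stays, rng)
        X = spec.encode(cov)
        fit = fit_logistic(X, y, spec=spec)
        ests = np.array([fit.params[f"duration[{lab}]"] for lab in ep.BIN_LABELS_2H])
        ses = np.array([fit.table.loc[f"duration[{lab}]", "se"]
                        for lab in ep.BIN_LABELS_2H])
        planted = np.array([RECOVERY_LADDER[lab] for lab in ep.BIN_LABELS_2H])
        covers = np.abs(ests - planted) <= z * ses
        monotone = bool(np.all(np.diff(ests) >= 0))
        for lab, e, s, c, t in zip(ep.BIN_LABELS_2H, ests, ses, covers, planted):
            rows.append({"replicate": rep, "bin": lab, "planted": t,
                         "estimate": e, "se": s, "covered": bool(c),
                         "monotone": monotone})
    return pd.DataFrame(rows)
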