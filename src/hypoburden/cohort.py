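"""Cohort construction: distributive-shock inclusion/exclusion rules.

A stay enters the analysis cohort when the patient was an adult on
continuous vasopressor support for at least six hours, with no marker of a
non-distributive shock state (cardiogenic shock / tamponade / pulmonary
embolus diagnoses, mechanical circulatory support procedures, excluded DRGs,
or massive red-cell transfusion), no long gap in MAP charting, and no second
otherwise-qualifying ICU stay in the same hospital admission.

Rules are applied in a fixed documented order and every removal is counted
in an exclusion ledger, so cohort flowcharts are comparable across runs.
The rules are conjunctive: reordering them changes per-rule counts but never
final membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .intervals import merge_intervals

log = logging.getLogger(__name__)

#: Default exclusion code lists (literal string matching on dot-stripped
#: ICD-9-CM / procedure / DRG codes).
DEFAULT_EXCLUSION_CODES = {
    "cardiogenic shock": {"type": "diagnosis", "codes": ["78551", "99801"]},
    "cardiac tamponade": {"type": "diagnosis", "codes": ["4233"]},
    "pulmonary embolus": {"type": "diagnosis", "codes": ["4151"]},
    "IABP/ECMO": {"type": "procedure", "codes": ["3761", "3965"]},
    "excluded DRG": {"type": "drg", "codes": ["104", "105", "110", "111"]},
}


def normalize_code(code) -> str:
    return str(code).replace(".", "").strip()


@dataclass
class ExclusionLedger:
    """Ordered per-rule removal counts with a conservation check."""

    initial_n: int
    rows: list[tuple[str, int]] = field(default_factory=list)

    def record(self, rule: str, removed: int) -> None:
        if removed < 0:
            raise DataError("negative removal count")
        self.rows.append((rule, removed))

    @property
    def final_n(self) -> int:
        return self.initial_n - sum(r for _, r in self.rows)

    def check(self) -> None:
        if self.final_n < 0:
            raise DataError("exclusion ledger does not conserve counts")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["rule", "removed"])
        df["remaining"] = self.initial_n - df["removed"].cumsum()
        return df

    def flowchart(self) -> str:
        lines = [f"ICU stays assessed: {self.initial_n}"]
        remaining = self.initial_n
        for rule, removed in self.rows:
            remaining -= removed
            lines.append(f"  - excluded ({rule}): {removed}  -> {remaining}")
        lines.append(f"Final cohort: {self.final_n}")
        return "\n".join(lines)


def qualifying_vasopressor_support(infusion_intervals: list[tuple[float, float]],
                                   min_hours: float = 6.0,
                                   gap_tolerance_minutes: float = 15.0
                                   ) -> tuple[list[tuple[float, float]], bool]:
    """Merged vasopressor-support intervals and the >= min_hours qualifier.

    Intervals across all drugs are unioned; neighbouring intervals separated
    by at most the gap tolerance are treated as continuous (pump swaps and
    charting seams routinely produce sub-quarter-hour gaps). The stay
    qualifies iff some merged interval spans at least ``min_hours`` (closed
    lower bound).
    """
    merged = merge_intervals(infusion_intervals, gap_tolerance_minutes / 60.0)
    qualifies = any(e - s >= min_hours - 1e-9 for s, e in merged)
    return merged, qualifies


def rbc_volume_exclusion(times, volumes_ml, threshold_ml: float = 3500.0,
                         window_hours: float = 48.0) -> bool:
    """True iff any 48-h window contains >= threshold_ml of red cells.

    The optimal window can be anchored at an event time, so scanning windows
    ``[t_i, t_i + window]`` (closed at both ends) over all events is exact.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes_ml, dtype=float)
    if np.any(v < 0):
        raise DataError("negative transfusion volume")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    for i in range(len(t)):
        in_window = (t >= t[i]) & (t <= t[i] + window_hours + 1e-9)
        if v[in_window].sum() >= threshold_ml - 1e-9:
            return True
    return False


def code_exclusion(stay_codes: list[tuple[str, str]],
                   rules: dict | None = None) -> tuple[bool, str | None]:
    """Match a stay's (type, code) pairs against the configured exclusion lists.

    Returns (excluded, first matching rule name). Matching is exact-string on
    dot-stripped codes; no ICD hierarchy expansion.
    """
    rules = DEFAULT_EXCLUSION_CODES if rules is None else rules
    if not rules:
        raise ConfigurationError("exclusion code lists are empty")
    for rule_name, spec in rules.items():
        wanted = {normalize_code(c) for c in spec["codes"]}
        for ctype, code in stay_codes:
            if ctype == spec["type"] and normalize_code(code) in wanted:
                return True, rule_name
    return False, None


def data_gap_exclusion(reading_times, icu_in: float, icu_out: float,
                       max_gap_hours: float = 24.0) -> bool:
    """True iff MAP charting leaves a gap longer than max_gap_hours.

    Gaps are measured between consecutive readings and at both edges of the
    stay; a stay with no readings at all is a gap by definition.
    """
    t = np.sort(np.asarray(reading_times, dtype=float))
    if len(t) == 0:
        return True
    boundaries = np.concatenate([[icu_in], t, [icu_out]])
    return bool(np.any(np.diff(boundaries) > max_gap_hours + 1e-9))


def icu_death(death_time: float | None, icu_out: float,
              icu_in: float | None = None, window_hours: float = 24.0) -> bool:
    """ICU-mortality attribution: death recorded within 24 h of ICU discharge.

    Patients without a death record, or dying later than the window, are
    considered alive at ICU discharge.
    """
    if death_time is None or (isinstance(death_time, float) and np.isnan(death_time)):
        return False
    if icu_in is not None and death_time < icu_in - 1e-9:
        raise DataError("death recorded before ICU admission")
    return bool(death_time <= icu_out + window_hours + 1e-9)


@dataclass
class CohortConfig:
    min_age_years: float = 18.0
    min_support_hours: float = 6.0
    gap_tolerance_minutes: float = 15.0
    rbc_threshold_ml: float = 3500.0
    rbc_window_hours: float = 48.0
    data_gap_hours: float = 24.0
    exclusion_codes: dict = field(default_factory=lambda: DEFAULT_EXCLUSION_CODES)


def stay_support_intervals(infusions: pd.DataFrame, config: CohortConfig
                           ) -> dict[object, list[tuple[float, float]]]:
    """Merged support intervals per stay (hours), warning on same-drug overlap."""
    out: dict[object, list[tuple[float, float]]] = {}
    for stay_id, grp in infusions.groupby("stay_id", sort=False):
        for drug, dg in grp.groupby("drug", sort=False):
            ivs = sorted(zip(dg["start"], dg["end"]))
            if any(b0 < a1 for (_, a1), (b0, _) in zip(ivs, ivs[1:])):
                log.warning("overlapping %s records for stay %s merged", drug, stay_id)
        merged, _ = qualifying_vasopressor_support(
            list(zip(grp["start"], grp["end"])),
            config.min_support_hours, config.gap_tolerance_minutes)
        out[stay_id] = merged
    return out


RULE_ORDER = ("age <18", "no continuous vasopressor support >=6 h",
              "exclusion code", "RBC >=3500 mL in 48 h",
              "gap in ICU stay data", "multiple qualifying stays in admission")


def select_cohort(stays: pd.DataFrame, infusions: pd.DataFrame,
                  map_readings: pd.DataFrame, transfusions: pd.DataFrame,
                  codes: pd.DataFrame, config: CohortConfig | None = None
                  ) -> tuple[pd.DataFrame, ExclusionLedger,
                             dict[object, list[tuple[float, float]]]]:
    """Apply all inclusion/exclusion rules in the documented order.

    Returns (cohort stays, ledger, merged support intervals per cohort stay).
    Times in all tables are float hours on a common clock.
    """
    config = config or CohortConfig()
    ledger = ExclusionLedger(initial_n=len(stays))
    alive = stays.copy()

    # 1. adults only
    keep = alive["age_years"] >= config.min_age_years
    ledger.record(RULE_ORDER[0], int((~keep).sum()))
    alive = alive[keep]

    # 2. continuous vasopressor support >= 6 h
    support = stay_support_intervals(infusions[infusions["stay_id"].isin(alive["stay_id"])],
                                     config)
    qualifies = {}
    for sid in alive["stay_id"]:
        merged = support.get(sid, [])
        qualifies[sid] = any(e - s >= config.min_support_hours - 1e-9 for s, e in merged)
    keep = alive["stay_id"].map(qualifies).fillna(False).astype(bool)
    ledger.record(RULE_ORDER[1], int((~keep).sum()))
    alive = alive[keep]

    # 3. diagnosis / procedure / DRG exclusion codes
    code_map = {sid: list(zip(g["code_type"], g["code"]))
                for sid, g in codes.groupby("stay_id", sort=False)}
    keep = alive["stay_id"].map(
        lambda sid: not code_exclusion(code_map.get(sid, []),
                                       config.exclusion_codes)[0]).astype(bool)
    ledger.record(RULE_ORDER[2], int((~keep).sum()))
    alive = alive[keep]

    # 4. massive red-cell transfusion
    tx_map = {sid: g for sid, g in transfusions.groupby("stay_id", sort=False)}
    def _rbc_ok(sid):
        g = tx_map.get(sid)
        if g is None or len(g) == 0:
            return True
        return not rbc_volume_exclusion(g["time"].to_numpy(), g["volume_ml"].to_numpy(),
                                        config.rbc_threshold_ml, config.rbc_window_hours)
    keep = alive["stay_id"].map(_rbc_ok).astype(bool)
    ledger.record(RULE_ORDER[3], int((~keep).sum()))
    alive = alive[keep]

    # 5. gaps in MAP charting
    rd_map = {sid: g["time"].to_numpy()
              for sid, g in map_readings.groupby("stay_id", sort=False)}
    stay_times = alive.set_index("stay_id")[["icu_in", "icu_out"]]
    def _gap_ok(sid):
        row = stay_times.loc[sid]
        return not data_gap_exclusion(rd_map.get(sid, np.empty(0)),
                                      float(row["icu_in"]), float(row["icu_out"]),
                                      config.data_gap_hours)
    keep = alive["stay_id"].map(_gap_ok).astype(bool)
    ledger.record(RULE_ORDER[4], int((~keep).sum()))
    alive = alive[keep]

    # 6. more than one otherwise-qualifying stay in the same hospital admission
    if len(alive):
        counts = alive.groupby("admission_id")["stay_id"].transform("count")
        keep = counts == 1
        ledger.record(RULE_ORDER[5], int((~keep).sum()))
        alive = alive[keep]
    else:
        ledger.record(RULE_ORDER[5], 0)

    ledger.check()
    support_final = {sid: support[sid] for sid in alive["stay_id"]}
    return alive.reset_index(drop=True), ledger, support_final
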