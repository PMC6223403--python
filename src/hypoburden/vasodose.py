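"""Norepinephrine-equivalent dose (NED) from multi-drug vasopressor infusions.

Concurrent vasopressor infusions are expressed on a common µg/kg/min
norepinephrine scale by fixed conversion factors and summed into a
piecewise-constant step function over time. From the step function we derive
the maximum dose reached during treatment, the Table-style dose bin, and the
"high-dose" subgroup flag (NED >= 0.2 µg/kg/min sustained over >= 6 h).

The conversion factors ship as configurable defaults rather than code
constants: equivalence tables differ slightly between sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .intervals import EPS

VASOPRESSOR_DRUGS = ("norepinephrine", "epinephrine", "dopamine",
                     "phenylephrine", "vasopressin")

#: NED conversion factors. For rates natively in µg/kg/min the factor is a
#: plain multiplier; vasopressin (U/min) converts with a factor already on
#: the per-kg-equivalent scale, so no weight enters.
DEFAULT_NED_FACTORS = {
    "norepinephrine": 1.0,
    "epinephrine": 1.0,
    "dopamine": 0.01,
    "phenylephrine": 0.1,
    "vasopressin": 2.5,  # µg/kg/min of norepinephrine per U/min
}

DOSE_BIN_EDGES = (0.2, 0.5, 1.0, 1.5, 2.0, 2.5)
DOSE_BIN_LABELS = ("0 to <0.2", ">=0.2 to <0.5", ">=0.5 to <1.0",
                   ">=1.0 to <1.5", ">=1.5 to <2.0", ">=2.0 to <2.5", ">=2.5")
DOSE_REFERENCE_BIN = DOSE_BIN_LABELS[0]


@dataclass
class InfusionRecord:
    stay_id: object
    drug: str
    start: float  # hours
    end: float
    rate: float
    unit: str  # 'ug/kg/min', 'ug/min', or 'U/min'

    def __post_init__(self):
        if self.drug not in VASOPRESSOR_DRUGS:
            raise DataError(f"unknown vasopressor drug: {self.drug!r}")
        if not self.end > self.start:
            raise DataError(f"infusion has start >= end for stay {self.stay_id!r}")
        if self.rate < 0:
            raise DataError(f"negative infusion rate for stay {self.stay_id!r}")


@dataclass
class NedSeries:
    """Summed NED step function: value ``values[i]`` on ``[times[i], times[i+1])``.

    Zero outside ``[times[0], times[-1])``; an empty series is identically 0.
    """

    stay_id: object
    times: np.ndarray   # breakpoints, length m+1
    values: np.ndarray  # length m

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        if len(self.values):
            idx = np.searchsorted(self.times, t, side="right") - 1
            inside = (idx >= 0) & (idx < len(self.values))
            out[inside] = self.values[idx[inside]]
        return out


def ned_rate(drug: str, rate: float, unit: str, weight_kg: float | None = None,
             factors: dict | None = None) -> float:
    """Convert one infusion rate to norepinephrine-equivalent µg/kg/min.

    µg/min rates are normalised by body weight before applying the factor;
    U/min (vasopressin) uses a factor already expressed per kg.
    """
    factors = DEFAULT_NED_FACTORS if factors is None else factors
    if drug not in factors:
        raise DataError(f"no NED conversion factor configured for drug {drug!r}")
    if rate < 0:
        raise DataError("negative infusion rate")
    f = factors[drug]
    if unit == "ug/kg/min":
        return rate * f
    if unit == "ug/min":
        if weight_kg is None or not np.isfinite(weight_kg) or weight_kg <= 0:
            raise DataError(f"weight required to normalise a µg/min rate for {drug}")
        return rate / weight_kg * f
    if unit == "U/min":
        if drug != "vasopressin":
            raise DataError(f"unit U/min is only valid for vasopressin, got {drug}")
        return rate * f
    raise DataError(f"unknown rate unit: {unit!r}")


def ned_step_function(infusions: list[InfusionRecord],
                      weight_kg: float | None = None,
                      factors: dict | None = None,
                      stay_id=None) -> NedSeries:
    """Sum concurrently running infusions into one NED step function.

    Breakpoints sit exactly at the record start/end times; at any time the
    value is the sum of converted rates over all records covering it.
    """
    if not infusions:
        return NedSeries(stay_id, np.empty(0), np.empty(0))
    if stay_id is None:
        stay_id = infusions[0].stay_id
    rates = [ned_rate(r.drug, r.rate, r.unit, weight_kg, factors) for r in infusions]
    times = np.unique(np.concatenate([[r.start for r in infusions],
                                      [r.end for r in infusions]]))
    values = np.zeros(len(times) - 1)
    for r, nr in zip(infusions, rates):
        i0 = int(np.searchsorted(times, r.start))
        i1 = int(np.searchsorted(times, r.end))
        values[i0:i1] += nr
    return NedSeries(stay_id, times, values)


def dose_bin(max_dose: float) -> str:
    if max_dose < 0:
        raise DataError("negative NED")
    return DOSE_BIN_LABELS[int(np.searchsorted(DOSE_BIN_EDGES, max_dose, side="right"))]


def max_ned(series: NedSeries) -> tuple[float, str]:
    """Peak of the step function and its Table-style dose bin."""
    peak = float(series.values.max()) if len(series.values) else 0.0
    return peak, dose_bin(peak)


def high_dose_flag(series: NedSeries, level: float = 0.2, span_hours: float = 6.0,
                   mode: str = "sustained") -> bool:
    """High-dose subgroup rule: NED >= level over a >= span_hours period.

    ``mode='sustained'`` (default) requires the step function to stay at or
    above ``level`` continuously for the span; ``mode='windowed'`` requires
    some window of exactly ``span_hours`` whose time-weighted mean NED is at
    or above ``level``.
    """
    if len(series.values) == 0:
        return False
    if mode == "sustained":
        run = 0.0
        for i in range(len(series.values)):
            if series.values[i] >= level - EPS:
                # contiguous with previous at-or-above segment?
                if i > 0 and series.values[i - 1] >= level - EPS:
                    run += series.times[i + 1] - series.times[i]
                else:
                    run = series.times[i + 1] - series.times[i]
                if run >= span_hours - EPS:
                    return True
            else:
                run = 0.0
        return False
    if mode == "windowed":
        return bool(_windowed_mean_max(series, span_hours) >= level - EPS)
    raise DataError(f"unknown high-dose mode: {mode!r}")


def _windowed_mean_max(series: NedSeries, span: float) -> float:
    """Max time-weighted mean of the step function over any window of length span.

    The maximising window can always be anchored so that one of its ends
    coincides with a breakpoint, so scanning windows starting at each
    breakpoint and ending at each breakpoint suffices.
    """
    t, v = series.times, series.values
    if t[-1] - t[0] < span - EPS:
        # pad with the implicit zeros outside the support of the series
        t = np.concatenate([[t[0] - span], t, [t[-1] + span]])
        v = np.concatenate([[0.0], v, [0.0]])
    cum = np.concatenate([[0.0], np.cumsum(v * np.diff(t))])

    def integral(a: float, b: float) -> float:
        # integral of the (zero-padded) step function over [a, b]
        a = min(max(a, t[0]), t[-1])
        b = min(max(b, t[0]), t[-1])
        ia = int(np.searchsorted(t, a, side="right") - 1)
        ib = int(np.searchsorted(t, b, side="right") - 1)
        ia = min(ia, len(v) - 1)
        ib = min(ib, len(v) - 1)
        full = cum[ib] - cum[ia]
        return full - (a - t[ia]) * v[ia] + (b - t[ib]) * v[ib]

    anchors = np.concatenate([t, t - span])
    best = 0.0
    for a in anchors:
        best = max(best, integral(a, a + span) / span)
    return best
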