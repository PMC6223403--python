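"""Descriptive estimands: hypotension prevalence and duration-binned mortality.

Three families of quantities:

* prevalence of a longest continuous below-threshold episode of at least
  d hours, tabulated over thresholds x minimum durations (and stratified by
  calendar era);
* ICU mortality by duration bin, with Wilson score 95% intervals;
* the per-2-h mortality trend: an n-weighted least-squares slope of bin
  mortality on bin midpoint, among stays with at least one episode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .episodes import (NEVER_BELOW, THRESHOLDS_MMHG, bin_labels, bin_midpoints,
                       duration_bin)
from .errors import DataError, UndefinedEstimateError

DEFAULT_MIN_DURATIONS = (2.0, 4.0, 8.0, 12.0, 16.0, 20.0)


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Inverts the score test: the interval is the set of p0 for which the
    observed k/n is not rejected at level alpha. Closed form:

        (p̂ + z²/2n ± z·sqrt(p̂(1-p̂)/n + z²/4n²)) / (1 + z²/n)
    """
    if n < 1:
        raise UndefinedEstimateError("Wilson interval undefined for n = 0")
    if not 0 <= k <= n:
        raise DataError("k must lie in [0, n]")
    z = stats.norm.ppf(1 - alpha / 2)
    phat = k / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    # the boundary cases are exact by construction; avoid cancellation dust
    lo = 0.0 if k == 0 else max(0.0, center - half)
    hi = 1.0 if k == n else min(1.0, center + half)
    return (lo, hi)


def _longest_col(threshold: float) -> str:
    return f"longest_{int(threshold)}"


def _ever_col(threshold: float) -> str:
    return f"ever_{int(threshold)}"


def prevalence_table(exposures: pd.DataFrame,
                     thresholds=THRESHOLDS_MMHG,
                     min_durations=DEFAULT_MIN_DURATIONS) -> pd.DataFrame:
    """Percent of the cohort with longest below-threshold episode >= d hours.

    Rows are thresholds (descending, the most permissive first); the first
    column is the ever-below percentage, then one column per minimum
    duration. Rows are nonincreasing left to right and columns nondecreasing
    with threshold by construction (set inclusion) — violations indicate a
    data defect upstream.
    """
    n = len(exposures)
    if n == 0:
        raise DataError("empty cohort")
    rows = {}
    for thr in sorted(thresholds, reverse=True):
        row = {"ever below": 100.0 * exposures[_ever_col(thr)].mean()}
        for d in min_durations:
            row[f">={d:g} h"] = 100.0 * (exposures[_longest_col(thr)] >= d - 1e-9).mean()
        rows[f"MAP <{int(thr)} mmHg"] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def mortality_by_bin(exposures: pd.DataFrame, outcomes: pd.Series,
                     threshold: float = 65.0, scheme: str = "2h",
                     alpha: float = 0.05) -> pd.DataFrame:
    """ICU mortality per duration bin with Wilson intervals.

    ``outcomes`` is a boolean Series indexed like ``exposures`` (one row per
    stay). Bins with no stays are reported with NaN rate, not 0%.
    """
    if len(outcomes) != len(exposures):
        raise DataError("one outcome per stay required")
    labels = exposures.apply(
        lambda r: duration_bin(r[_longest_col(threshold)], r[_ever_col(threshold)], scheme),
        axis=1)
    y = np.asarray(outcomes, dtype=bool)
    recs = []
    for lab in bin_labels(scheme):
        mask = (labels == lab).to_numpy()
        n = int(mask.sum())
        k = int(y[mask].sum())
        if n:
            lo, hi = wilson_interval(k, n, alpha)
            rate = k / n
        else:
            rate, lo, hi = np.nan, np.nan, np.nan
        recs.append({"bin": lab, "n": n, "deaths": k, "rate": rate,
                     "wilson_lo": lo, "wilson_hi": hi})
    return pd.DataFrame(recs).set_index("bin")


def dichotomous_contrast(exposures: pd.DataFrame, outcomes: pd.Series,
                         threshold: float = 65.0, cut_hours: float = 2.0,
                         include_never_in_short: bool = False) -> dict:
    """Mortality for longest episode < cut vs >= cut hours.

    By default the short group requires at least one episode (never-below
    stays are excluded); a switch includes them, since either reading of
    "longest episode < 2 h" is defensible.
    """
    longest = exposures[_longest_col(threshold)]
    ever = exposures[_ever_col(threshold)].astype(bool)
    y = np.asarray(outcomes, dtype=bool)
    exposed = ever | (longest > 0)
    short = (longest < cut_hours) & (exposed if not include_never_in_short else True)
    long_ = longest >= cut_hours - 1e-9
    out = {}
    for name, mask in (("short", short.to_numpy()), ("long", long_.to_numpy())):
        n, k = int(mask.sum()), int(y[mask].sum())
        out[name] = {"n": n, "deaths": k, "rate": k / n if n else np.nan}
    if out["short"]["n"] and out["long"]["n"]:
        tbl = [[out["long"]["deaths"], out["long"]["n"] - out["long"]["deaths"]],
               [out["short"]["deaths"], out["short"]["n"] - out["short"]["deaths"]]]
        out["p_value"] = float(stats.chi2_contingency(tbl, correction=False)[1])
    return out


def trend_slope(bin_mort: pd.DataFrame, scheme: str = "2h") -> float:
    """Weighted LS slope of bin mortality on bin midpoint, in pp per 2 h.

    Only exposed bins (never-below excluded) with n >= 1 enter; weights are
    bin sizes. Requires at least two nonempty bins.
    """
    mids = bin_midpoints(scheme)
    rows = bin_mort.drop(index=NEVER_BELOW, errors="ignore")
    rows = rows[rows["n"] > 0]
    if len(rows) < 2:
        raise UndefinedEstimateError("trend slope needs >= 2 nonempty exposed bins")
    x = np.array([mids[lab] for lab in rows.index], dtype=float)
    y = rows["rate"].to_numpy(dtype=float) * 100.0  # percentage points
    w = rows["n"].to_numpy(dtype=float)
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    denom = np.sum(w * (x - xbar) ** 2)
    if denom <= 0:
        raise UndefinedEstimateError("degenerate design: all bins share one midpoint")
    slope_per_hour = np.sum(w * (x - xbar) * (y - ybar)) / denom
    return float(slope_per_hour * 2.0)


def stratify_era(exposures: pd.DataFrame, era: pd.Series,
                 thresholds=THRESHOLDS_MMHG,
                 min_durations=DEFAULT_MIN_DURATIONS) -> dict[str, pd.DataFrame]:
    """Prevalence tables for the full cohort and each calendar-era stratum."""
    if era.isna().any():
        raise DataError("era flag missing for some stays")
    out = {"all": prevalence_table(exposures, thresholds, min_durations)}
    for stratum in ("pre2008", "post2008"):
        mask = (era == stratum).to_numpy()
        if mask.any():
            out[stratum] = prevalence_table(exposures[mask], thresholds, min_durations)
        else:
            out[stratum] = None
    return out
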