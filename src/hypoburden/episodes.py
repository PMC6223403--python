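"""Hypotension-episode detection on irregularly sampled MAP readings.

The exposure of interest is the *longest continuous episode* with mean
arterial pressure (MAP) below a threshold while the patient is on
vasopressor support. MAP is charted roughly hourly, so "continuous" has to
be operationalised on discrete readings: we reconstruct a piecewise-constant
state by carrying each reading forward until the next reading, or until a
maximum carry-forward gap elapses, whichever comes first. Beyond the gap the
state is undefined and any running episode is broken (conservative: long
charting gaps never inflate an episode). Episodes are clipped to the
vasopressor-support intervals; hypotension off support does not count.

All times are float hours on a shared clock; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .intervals import EPS, intersect_intervals, merge_intervals, total_length

THRESHOLDS_MMHG = (55.0, 60.0, 65.0, 75.0, 80.0)

#: Primary duration-bin scheme: right-open 2-h bins, wider above 12 h.
BIN_EDGES_2H = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0)
BIN_LABELS_2H = (
    ">0 to <2", ">=2 to <4", ">=4 to <6", ">=6 to <8", ">=8 to <10",
    ">=10 to <12", ">=12 to <16", ">=16 to <20", ">=20",
)
#: Sensitivity scheme with 6-h bins.
BIN_EDGES_6H = (6.0, 12.0, 24.0)
BIN_LABELS_6H = (">0 to <6", ">=6 to <12", ">=12 to <24", ">=24")

NEVER_BELOW = "never below"

BIN_SCHEMES = {
    "2h": (BIN_EDGES_2H, BIN_LABELS_2H),
    "6h": (BIN_EDGES_6H, BIN_LABELS_6H),
}


@dataclass
class MapState:
    """Piecewise-constant MAP state: value ``values[i]`` on ``[starts[i], ends[i])``.

    Segments are sorted and non-overlapping; a gap between ``ends[i]`` and
    ``starts[i+1]`` means the state is undefined there.
    """

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    n_dropped: int = 0  # implausible readings removed

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class Episode:
    """One maximal below-threshold run inside vasopressor support."""

    start: float
    end: float
    threshold: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def clean_readings(times, values, plausible_mmhg=(10.0, 250.0)):
    """Sort readings, average simultaneous duplicates, drop implausible values.

    Returns (times, values, n_dropped). Duplicate timestamps are averaged
    (charting systems occasionally double-write); values outside the
    plausible range are treated as artefact and removed.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise DataError("reading times and values differ in length")
    ok = (v >= plausible_mmhg[0]) & (v <= plausible_mmhg[1])
    n_dropped = int((~ok).sum())
    t, v = t[ok], v[ok]
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if len(t) > 1:
        # average runs of identical timestamps
        uniq, inverse = np.unique(t, return_inverse=True)
        if len(uniq) < len(t):
            sums = np.zeros(len(uniq))
            counts = np.zeros(len(uniq))
            np.add.at(sums, inverse, v)
            np.add.at(counts, inverse, 1.0)
            t, v = uniq, sums / counts
    return t, v, n_dropped


def map_state_function(times, values, max_gap_hours: float = 1.5,
                       plausible_mmhg=(10.0, 250.0)) -> MapState:
    """Carry-forward reconstruction of the MAP state from point readings.

    Reading ``i`` defines the state on ``[t_i, min(t_{i+1}, t_i + max_gap))``.
    The state is undefined before the first and from the last reading onward,
    and inside any carry-forward window that expires before the next reading.
    """
    if max_gap_hours <= 0:
        raise DataError("max_gap_hours must be positive")
    t, v, n_dropped = clean_readings(times, values, plausible_mmhg)
    if len(t) < 2:
        return MapState(np.empty(0), np.empty(0), np.empty(0), n_dropped)
    starts = t[:-1]
    ends = np.minimum(t[1:], t[:-1] + max_gap_hours)
    vals = v[:-1]
    return MapState(starts, ends, vals, n_dropped)


def below_runs(state: MapState, threshold: float,
               support: list[tuple[float, float]]) -> list[Episode]:
    """Maximal intervals where the state is defined, < threshold, and on support.

    Runs are broken by any at-or-above reading, by undefined gaps, and by
    support boundaries (partial overlap keeps only the overlapping part).
    """
    if len(state) == 0 or not support:
        return []
    # touching/overlapping support intervals are continuous support
    support = merge_intervals(list(support), 0.0)
    below = state.values < threshold
    raw: list[tuple[float, float]] = []
    for i in np.flatnonzero(below):
        s, e = state.starts[i], state.ends[i]
        if raw and s - raw[-1][1] <= EPS:
            raw[-1] = (raw[-1][0], e)
        else:
            raw.append((float(s), float(e)))
    clipped = intersect_intervals(raw, support)
    return [Episode(s, e, threshold) for s, e in clipped]


def longest_below(episodes: list[Episode]) -> float:
    """Longest episode duration in hours; 0 if there are none."""
    return max((ep.duration for ep in episodes), default=0.0)


def cumulative_below(episodes: list[Episode]) -> float:
    """Total below-threshold time in hours across all episodes."""
    return float(sum(ep.duration for ep in episodes))


def ever_below(times, values, threshold: float,
               support: list[tuple[float, float]]) -> bool:
    """True iff any *reading* taken during support is strictly below threshold."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    for s, e in support:
        in_sup = (t >= s - EPS) & (t < e - EPS)
        if np.any(v[in_sup] < threshold):
            return True
    return False


def duration_bin(longest_duration: float, ever: bool, scheme: str = "2h") -> str:
    """Categorical exposure label for a stay's longest episode.

    Stays that never dipped below threshold get the reference label; a stay
    with a below-threshold reading but zero measurable run length (e.g. the
    dip was the final reading) falls in the lowest exposed bin.
    """
    if longest_duration < 0:
        raise DataError("negative episode duration")
    if scheme not in BIN_SCHEMES:
        raise DataError(f"unknown bin scheme: {scheme!r}")
    if longest_duration <= 0 and not ever:
        return NEVER_BELOW
    edges, labels = BIN_SCHEMES[scheme]
    return labels[int(np.searchsorted(edges, longest_duration, side="right"))]


def bin_labels(scheme: str = "2h", include_reference: bool = True) -> list[str]:
    edges, labels = BIN_SCHEMES[scheme]
    return ([NEVER_BELOW] if include_reference else []) + list(labels)


def bin_midpoints(scheme: str = "2h") -> dict[str, float]:
    """Midpoint in hours of each exposed bin (for trend fitting).

    The open-ended top bin is assigned its lower edge plus half the width of
    the preceding bin.
    """
    edges, labels = BIN_SCHEMES[scheme]
    lo = (0.0,) + edges
    mids = {}
    for i, lab in enumerate(labels):
        if i < len(edges):
            mids[lab] = (lo[i] + edges[i]) / 2.0
        else:
            mids[lab] = edges[-1] + (edges[-1] - edges[-2]) / 2.0
    return mids


def baseline_map(times, values, vasopressor_start: float,
                 lookback_hours: float = 1.0) -> float | None:
    """Last MAP reading within the lookback window ending at vasopressor start.

    A reading exactly at the start time is used. Returns None when no reading
    falls in the window — missingness is a first-class category downstream.
    """
    t, v, _ = clean_readings(times, values)
    in_window = (t >= vasopressor_start - lookback_hours - EPS) & (t <= vasopressor_start + EPS)
    idx = np.flatnonzero(in_window)
    if len(idx) == 0:
        return None
    return float(v[idx[-1]])


BASELINE_MAP_CATS = ("<65", ">=65", "missing")


def baseline_map_category(value: float | None) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    return "<65" if value < 65.0 else ">=65"


@dataclass
class ExposureSummary:
    """Per-stay hypotension burden at every analysis threshold."""

    stay_id: object
    per_threshold: dict[float, dict] = field(default_factory=dict)
    baseline_map_mmhg: float | None = None
    total_support_hours: float = 0.0

    def bin_label(self, threshold: float, scheme: str = "2h") -> str:
        rec = self.per_threshold[threshold]
        return duration_bin(rec["longest"], rec["ever"], scheme)


def summarize_stay(stay_id, times, values, support,
                   thresholds=THRESHOLDS_MMHG, max_gap_hours: float = 1.5,
                   vasopressor_start: float | None = None,
                   lookback_hours: float = 1.0) -> ExposureSummary:
    """Full burden summary for one stay: per-threshold longest/cumulative/ever.

    ``support`` must already be the merged vasopressor-support intervals.
    """
    state = map_state_function(times, values, max_gap_hours)
    support = merge_intervals(list(support), 0.0)
    summary = ExposureSummary(stay_id=stay_id, total_support_hours=total_length(support))
    for thr in thresholds:
        eps = below_runs(state, thr, support)
        summary.per_threshold[thr] = {
            "ever": ever_below(times, values, thr, support),
            "longest": longest_below(eps),
            "cumulative": cumulative_below(eps),
            "n_episodes": len(eps),
        }
    if vasopressor_start is not None:
        summary.baseline_map_mmhg = baseline_map(times, values, vasopressor_start,
                                                 lookback_hours)
    return summary
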