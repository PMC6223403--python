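"""Half-open interval arithmetic on float time axes.

Every interval in this package is ``[start, end)`` with times expressed as
float hours on a common clock. These helpers are deliberately tiny and
allocation-light: episode detection calls them once per stay.
"""

from __future__ import annotations

import numpy as np

# Tolerance for treating two breakpoints as coincident. Event times are
# minute-aligned in practice, so 1e-9 h (~3.6 µs) is far below the data scale.
EPS = 1e-9


def merge_intervals(intervals: list[tuple[float, float]], gap_tolerance: float = 0.0
                    ) -> list[tuple[float, float]]:
    """Union of intervals, fusing neighbours separated by <= gap_tolerance.

    Zero-length inputs are dropped. Output is sorted and pairwise disjoint
    with gaps strictly greater than ``gap_tolerance``.
    """
    ivs = sorted((s, e) for s, e in intervals if e - s > EPS)
    out: list[tuple[float, float]] = []
    for s, e in ivs:
        if out and s - out[-1][1] <= gap_tolerance + EPS:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: list[tuple[float, float]], b: list[tuple[float, float]]
                        ) -> list[tuple[float, float]]:
    """Pairwise intersection of two sorted disjoint interval lists."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e - s > EPS:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: list[tuple[float, float]]) -> float:
    return float(sum(e - s for s, e in intervals))


def point_in_intervals(t: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Vectorised membership test for half-open intervals."""
    t = np.asarray(t, dtype=float)
    mask = np.zeros(t.shape, dtype=bool)
    for s, e in intervals:
        mask |= (t >= s - EPS) & (t < e - EPS)
    return mask
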