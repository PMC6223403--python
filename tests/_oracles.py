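"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — dense 1-minute grids, exhaustive
window scans, a from-scratch IRLS solver, numeric root-finding — and shares
no code with the package's own algorithms.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm


def grid_episode_oracle(reading_minutes, values, threshold, support_minutes,
                        max_gap_minutes):
    """Minute-grid episode detection under the carry-forward convention.

    All inputs are integer minutes. Minute m is "below" iff some reading at
    t_i <= m with a successor reading satisfies m < t_{i+1}, m - t_i <
    max_gap, value_i < threshold, and [m, m+1) lies in a support interval.
    Returns (longest_minutes, cumulative_minutes, episodes as minute pairs).
    """
    t = np.asarray(reading_minutes, dtype=int)
    v = np.asarray(values, dtype=float)
    if len(t) < 2 or not support_minutes:
        return 0, 0, []
    lo, hi = t[0], t[-1]
    below = np.zeros(hi - lo, dtype=bool)
    for m in range(lo, hi):
        i = int(np.searchsorted(t, m, side="right")) - 1
        if i < 0 or i >= len(t) - 1:
            continue
        if m - t[i] >= max_gap_minutes:
            continue
        if v[i] >= threshold:
            continue
        if any(s <= m and m + 1 <= e for s, e in support_minutes):
            below[m - lo] = True
    padded = np.concatenate([[False], below, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = ends - starts
    episodes = [(lo + s, lo + e) for s, e in zip(starts, ends)]
    longest = int(runs.max()) if len(runs) else 0
    return longest, int(runs.sum()), episodes


def grid_ned_oracle(records, times):
    """Pointwise NED by direct summation over records covering each time."""
    out = np.zeros(len(times))
    for j, t in enumerate(times):
        out[j] = sum(r["ned"] for r in records if r["start"] <= t < r["end"])
    return out


def brute_force_window_sum(times, volumes, threshold, window):
    """Exhaustive check over every pair-defined closed window of length <= window."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes, dtype=float)
    n = len(t)
    for i in range(n):
        for j in range(n):
            if 0 <= t[j] - t[i] <= window:
                total = v[(t >= t[i]) & (t <= t[j])].sum()
                if total >= threshold:
                    return True
    return False


def grid_sustained_oracle(bp_times, bp_values, level, span_minutes):
    """Minute-grid check that a step function stays >= level for >= span."""
    t0, t1 = bp_times[0], bp_times[-1]
    minutes = np.arange(int(round(t0 * 60)), int(round(t1 * 60)))
    run = 0
    for m in minutes:
        tm = (m + 0.5) / 60.0
        i = int(np.searchsorted(bp_times, tm, side="right")) - 1
        val = bp_values[i] if 0 <= i < len(bp_values) else 0.0
        run = run + 1 if val >= level else 0
        if run >= span_minutes:
            return True
    return False


def irls_logistic(X, y, tol=1e-12, maxiter=200):
    """From-scratch iteratively reweighted least squares for logistic MLE.

    Returns (beta, se) with observed-information standard errors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = X.T @ (X * (mu * (1 - mu))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


def wilson_by_inversion(k, n, alpha=0.05):
    """Wilson bounds by numeric root-finding of the score equation."""
    z = norm.ppf(1 - alpha / 2)
    phat = k / n

    def score(p):
        return (phat - p) ** 2 - z * z * p * (1 - p) / n

    # score() also vanishes at p = phat itself, so the brackets must start
    # strictly inside the interval on the far side of that trivial root
    lo = 0.0 if k == 0 else brentq(score, 1e-12, phat * (1 - 1e-12), xtol=1e-14)
    hi = 1.0 if k == n else brentq(score, phat + (1 - phat) * 1e-12, 1 - 1e-12,
                                   xtol=1e-14)
    return lo, hi


def random_stay(rng, minutes_span=(600, 6000)):
    """A random minute-aligned stay: readings, support intervals, max-gap.

    Values are drawn to straddle all analysis thresholds; support is 1-3
    disjoint minute-aligned intervals; gaps occasionally exceed the
    carry-forward cap so undefined stretches are exercised.
    """
    span = int(rng.integers(*minutes_span))
    times = [0]
    while times[-1] < span:
        g = int(rng.integers(10, 200))  # some gaps exceed any max-gap cap
        times.append(times[-1] + g)
    times = np.array(times[:-1] if times[-1] >= span else times, dtype=int)
    if len(times) < 2:
        times = np.array([0, 60], dtype=int)
    values = rng.uniform(40, 95, size=len(times)).round(0)
    n_sup = int(rng.integers(1, 4))
    cuts = np.sort(rng.integers(0, span, size=2 * n_sup))
    support = [(int(a), int(b)) for a, b in zip(cuts[::2], cuts[1::2]) if b > a]
    max_gap = int(rng.choice([60, 90, 120]))
    return times, values, support, max_gap
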