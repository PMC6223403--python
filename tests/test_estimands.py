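"""Wilson intervals, prevalence tables, bin mortality, and the trend slope."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from hypoburden import estimands as es
from hypoburden.errors import DataError, UndefinedEstimateError

from _oracles import wilson_by_inversion


class TestWilsonInterval:
    def test_zero_successes_lower_bound_exactly_zero(self):
        lo, hi = es.wilson_interval(0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_symmetric_about_half(self):
        lo, hi = es.wilson_interval(5, 10)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_matches_numeric_score_inversion(self):
        for n in (1, 5, 10, 37, 200, 5000):
            for k in {0, 1, n // 3, n // 2, n - 1, n}:
                if not 0 <= k <= n:
                    continue
                lo, hi = es.wilson_interval(k, n)
                olo, ohi = wilson_by_inversion(k, n)
                assert lo == pytest.approx(olo, abs=1e-10)
                assert hi == pytest.approx(ohi, abs=1e-10)

    def test_matches_statsmodels(self):
        lo, hi = es.wilson_interval(37, 120)
        slo, shi = proportion_confint(37, 120, method="wilson")
        assert (lo, hi) == pytest.approx((slo, shi), abs=1e-12)

    def test_contains_point_estimate_and_shrinks_with_n(self):
        for k, n in ((3, 10), (30, 100), (300, 1000)):
            lo, hi = es.wilson_interval(k, n)
            assert lo <= k / n <= hi
        w = [es.wilson_interval(3 * m, 10 * m) for m in (1, 10, 100)]
        widths = [hi - lo for lo, hi in w]
        assert widths[0] > widths[1] > widths[2]

    def test_undefined_for_empty_sample(self):
        with pytest.raises(UndefinedEstimateError):
            es.wilson_interval(0, 0)


def make_exposures(longest_by_thr, n):
    """Exposure frame where every stay shares the given per-threshold longest."""
    data = {"stay_id": np.arange(n)}
    for thr, dur in longest_by_thr.items():
        data[f"longest_{thr}"] = np.full(n, dur)
        data[f"ever_{thr}"] = np.full(n, dur > 0)
    return pd.DataFrame(data)


class TestPrevalenceTable:
    def test_constructed_uniform_cohort(self):
        exp = make_exposures({55: 0.0, 60: 0.0, 65: 3.0, 75: 3.0, 80: 3.0}, 20)
        tab = es.prevalence_table(exp)
        row = tab.loc["MAP <65 mmHg"]
        assert row["ever below"] == 100.0
        assert row[">=2 h"] == 100.0
        assert row[">=4 h"] == 0.0
        assert tab.loc["MAP <55 mmHg"].sum() == 0.0

    def test_monotone_both_axes_and_recount_oracle(self, rng):
        n = 300
        base = rng.exponential(4.0, size=n)
        data = {"stay_id": np.arange(n)}
        for j, thr in enumerate((55, 60, 65, 75, 80)):
            dur = base * (0.4 + 0.2 * j)  # longer runs at higher thresholds
            data[f"longest_{thr}"] = dur
            data[f"ever_{thr}"] = dur > 0.5
        exp = pd.DataFrame(data)
        tab = es.prevalence_table(exp)
        vals = tab.to_numpy()
        assert (np.diff(vals[:, 1:], axis=1) <= 1e-9).all()   # rows nonincreasing
        assert (np.diff(vals, axis=0) <= 1e-9).all()          # 80 at top, 55 at bottom
        # independent recount of one cell
        want = 100.0 * np.mean(exp["longest_65"] >= 8.0)
        assert tab.loc["MAP <65 mmHg", ">=8 h"] == pytest.approx(want)

    def test_empty_cohort_rejected(self):
        with pytest.raises(DataError):
            es.prevalence_table(make_exposures({65: 1.0}, 0), thresholds=(65,))


class TestMortalityByBin:
    @pytest.fixture()
    def toy(self):
        longest = np.repeat([0.0, 1.0, 3.0], 10)
        exp = pd.DataFrame({"stay_id": np.arange(30), "longest_65": longest,
                            "ever_65": longest > 0})
        deaths = np.r_[np.zeros(10), np.r_[np.ones(1), np.zeros(9)],
                       np.r_[np.ones(3), np.zeros(7)]]
        return exp, pd.Series(deaths.astype(bool))

    def test_rates_are_direct_division(self, toy):
        exp, y = toy
        bm = es.mortality_by_bin(exp, y)
        assert bm.loc["never below", "rate"] == pytest.approx(0.0)
        assert bm.loc[">0 to <2", "rate"] == pytest.approx(0.1)
        assert bm.loc[">=2 to <4", "rate"] == pytest.approx(0.3)
        assert (bm["n"].sum(), bm["deaths"].sum()) == (30, 4)

    def test_empty_bin_reported_as_nan_not_zero(self, toy):
        exp, y = toy
        bm = es.mortality_by_bin(exp, y)
        assert bm.loc[">=20", "n"] == 0
        assert np.isnan(bm.loc[">=20", "rate"])

    def test_wilson_bounds_contain_rate(self, toy):
        exp, y = toy
        bm = es.mortality_by_bin(exp, y).dropna()
        assert ((bm["wilson_lo"] <= bm["rate"]) & (bm["rate"] <= bm["wilson_hi"])).all()

    def test_dichotomous_contrast_excludes_never_by_default(self, toy):
        exp, y = toy
        c = es.dichotomous_contrast(exp, y)
        assert c["short"]["n"] == 10 and c["long"]["n"] == 10
        c2 = es.dichotomous_contrast(exp, y, include_never_in_short=True)
        assert c2["short"]["n"] == 20


class TestTrendSlope:
    def test_exactly_linear_rates_recovered(self):
        bm = pd.DataFrame({"n": [10, 10, 10], "rate": [0.10, 0.15, 0.20]},
                          index=[">0 to <2", ">=2 to <4", ">=4 to <6"])
        # midpoints 1,3,5 h; 2.5 pp per hour -> 5.0 pp per 2 h
        assert es.trend_slope(bm) == pytest.approx(5.0)

    def test_constant_rates_give_zero_slope(self):
        bm = pd.DataFrame({"n": [5, 50, 7], "rate": [0.3, 0.3, 0.3]},
                          index=[">0 to <2", ">=4 to <6", ">=20"])
        assert es.trend_slope(bm) == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        from hypoburden.episodes import BIN_LABELS_2H, bin_midpoints
        mids = bin_midpoints("2h")
        for _ in range(50):
            labs = list(BIN_LABELS_2H)
            n = rng.integers(1, 500, size=len(labs))
            rates = rng.uniform(0, 1, size=len(labs))
            bm = pd.DataFrame({"n": n, "rate": rates}, index=labs)
            x = np.array([mids[l] for l in labs])
            X = np.column_stack([np.ones_like(x), x])
            W = np.diag(n.astype(float))
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ (rates * 100))
            assert es.trend_slope(bm) == pytest.approx(2.0 * beta[1], rel=1e-9)

    def test_single_bin_is_undefined(self):
        bm = pd.DataFrame({"n": [10], "rate": [0.1]}, index=[">0 to <2"])
        with pytest.raises(UndefinedEstimateError):
            es.trend_slope(bm)


class TestStratifyEra:
    def test_strata_partition_and_match_subset_recount(self, rng):
        n = 200
        exp = make_exposures({55: 0, 60: 0, 65: 0, 75: 0, 80: 0}, n)
        for thr in (55, 60, 65, 75, 80):
            dur = rng.exponential(3, size=n)
            exp[f"longest_{thr}"] = dur
            exp[f"ever_{thr}"] = dur > 1
        era = pd.Series(np.where(rng.random(n) < 0.6, "pre2008", "post2008"))
        strata = es.stratify_era(exp, era)
        pre = es.prevalence_table(exp[(era == "pre2008").to_numpy()])
        pd.testing.assert_frame_equal(strata["pre2008"], pre)

    def test_single_era_gives_empty_stratum(self):
        exp = make_exposures({65: 1.0}, 10)
        strata = es.stratify_era(exp, pd.Series(["pre2008"] * 10), thresholds=(65,))
        assert strata["post2008"] is None
        assert len(strata["pre2008"]) == 1

    def test_missing_era_rejected(self):
        exp = make_exposures({65: 1.0}, 3)
        with pytest.raises(DataError):
            es.stratify_era(exp, pd.Series(["pre2008", None, "post2008"]),
                            thresholds=(65,))
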