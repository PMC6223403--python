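"""Generator contracts: determinism, planted truth, AR(1) statistics, outcomes."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from hypoburden import episodes as ep
from hypoburden.errors import ConfigurationError
from hypoburden.synthetic import (MapParams, SimConfig, assign_outcome,
                                  simulate_cohort, simulate_latent_path,
                                  simulate_map_series,
                                  simulate_regression_replicate)


def table_digest(tables):
    h = hashlib.sha256()
    for name in sorted(tables):
        h.update(name.encode())
        h.update(tables[name].to_csv(index=False).encode())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        t1, tr1 = simulate_cohort(SimConfig(n_stays=80, seed=123))
        t2, tr2 = simulate_cohort(SimConfig(n_stays=80, seed=123))
        assert table_digest(t1) == table_digest(t2)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_different_seed_differs(self):
        t1, _ = simulate_cohort(SimConfig(n_stays=80, seed=123))
        t2, _ = simulate_cohort(SimConfig(n_stays=80, seed=124))
        assert table_digest(t1) != table_digest(t2)

    def test_identical_rng_state_identical_series(self):
        p = MapParams()
        a = simulate_map_series(0.0, 48.0, p, np.random.default_rng(7))
        b = simulate_map_series(0.0, 48.0, p, np.random.default_rng(7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestEmptyAndInvalidConfig:
    def test_zero_stays_all_tables_empty(self):
        tables, truth = simulate_cohort(SimConfig(n_stays=0))
        assert all(len(df) == 0 for df in tables.values())
        assert len(truth) == 0

    @pytest.mark.parametrize("kw", [
        {"n_stays": -1},
        {"los_median_hours": -5.0},
        {"late_death_prob": 1.5},
    ])
    def test_invalid_scalar_fields_named(self, kw):
        with pytest.raises(ConfigurationError):
            SimConfig(**kw).validate()

    def test_invalid_phi_rejected(self):
        cfg = SimConfig()
        cfg.map.ar1_phi = 1.2
        with pytest.raises(ConfigurationError, match="phi"):
            cfg.validate()

    def test_nonpositive_sampling_interval_rejected(self):
        p = MapParams(sampling_interval_mean=-5.0)
        with pytest.raises(ConfigurationError):
            simulate_map_series(0.0, 24.0, p, np.random.default_rng(0))


class TestMapSeries:
    def test_reading_times_strictly_increasing_inside_stay(self, rng):
        t, v, path = simulate_map_series(10.0, 90.0, MapParams(), rng)
        assert (np.diff(t) > 0).all()
        assert t[0] >= 10.0 and t[-1] < 90.0
        assert len(path) == 80 * 60

    def test_high_baseline_no_dips_never_below_80(self, rng):
        p = MapParams(mean_range=(95.0, 96.0), noise_sd=0.5, ar1_phi=0.5,
                      dip_prob=0.0, artifact_rate=0.0)
        # stationary SD ~0.58 mmHg: a 15-mmHg excursion is a >25-sigma event
        t, v, _ = simulate_map_series(0.0, 72.0, p, rng)
        assert (v > 80.0).all()

    def test_ar1_stationary_variance_closed_form(self, rng):
        p = MapParams(ar1_phi=0.8, noise_sd=5.0)
        path = simulate_latent_path(400_000, 0.0, p, rng)
        want = 25.0 / (1.0 - 0.64)
        assert np.var(path) == pytest.approx(want, rel=0.05)

    def test_sampling_interval_mean_matches_config(self, rng):
        t, _, _ = simulate_map_series(0.0, 300.0, MapParams(), rng)
        gaps_min = np.diff(t) * 60.0
        assert np.mean(gaps_min) == pytest.approx(47.5, abs=3.0)
        assert gaps_min.min() >= 15.0 - 1e-9 and gaps_min.max() <= 90.0 + 1e-9


class TestAssignOutcome:
    REF = {"baseline_map": ">=65", "duration": "never below", "dose": "0 to <0.2",
           "age": "<65", "sex": "male", "sepsis": "no", "sofa": "<=4",
           "hypertension": "no", "ventilated": "no", "rrt": "no",
           "albumin": ">=2.5", "creatinine": "<2.0", "lactate": "<2.0"}

    def test_null_model_long_run_death_rate_is_half(self, rng):
        coefs = {"intercept": 0.0}
        deaths = [assign_outcome(self.REF, coefs, rng, 0.0, 100.0)["icu_death"]
                  for _ in range(4000)]
        assert np.mean(deaths) == pytest.approx(0.5, abs=0.03)

    def test_huge_negative_intercept_no_deaths(self, rng):
        coefs = {"intercept": -50.0}
        out = [assign_outcome(self.REF, coefs, rng, 0.0, 100.0, late_death_prob=0.0)
               for _ in range(500)]
        assert not any(o["icu_death"] for o in out)
        assert not any(o["day28_death"] for o in out)

    def test_icu_death_timestamp_within_recovery_window(self, rng):
        coefs = {"intercept": 50.0}
        for _ in range(50):
            o = assign_outcome(self.REF, coefs, rng, 0.0, 100.0)
            assert o["icu_death"] and 100.0 <= o["death_time"] <= 124.0

    def test_missing_coefficient_for_present_bin_rejected(self, rng):
        cats = dict(self.REF, duration=">=20")
        with pytest.raises(ConfigurationError, match="duration"):
            assign_outcome(cats, {"intercept": 0.0}, rng, 0.0, 100.0)

    def test_planted_bin_probabilities_match_empirical_rates(self, rng):
        """Monte-Carlo: empirical death rates per duration bin agree with the
        planted logistic probabilities within binomial error at n=20,000."""
        cov, y, p = simulate_regression_replicate(20_000, rng)
        df = pd.DataFrame({"bin": cov["duration"], "y": y, "p": p})
        g = df.groupby("bin", observed=True)
        for lab, sub in g:
            n = len(sub)
            se = np.sqrt(sub["p"].mean() * (1 - sub["p"].mean()) / n)
            assert abs(sub["y"].mean() - sub["p"].mean()) < 4 * se


class TestTruthConsistency:
    def test_recovered_durations_approach_latent_truth_with_denser_sampling(self):
        """The carry-forward estimate converges to the latent-path truth as
        the sampling interval shrinks."""
        errs = {}
        for interval in (60.0, 5.0):
            rng = np.random.default_rng(77)
            p = MapParams(sampling_interval_mean=interval,
                          sampling_interval_jitter=min(2.0, interval / 4),
                          sampling_interval_bounds=(1.0, interval * 2),
                          artifact_rate=0.0)
            diffs = []
            for _ in range(25):
                t, v, path = simulate_map_series(0.0, 100.0, p, rng,
                                                 support=[(0.0, 100.0)])
                from hypoburden.synthetic import latent_longest_below
                truth = latent_longest_below(path, 0.0, [(0.0, 100.0)], 65.0)
                state = ep.map_state_function(t, v, max_gap_hours=max(1.5, interval / 30))
                got = ep.longest_below(ep.below_runs(state, 65.0, [(0.0, 100.0)]))
                diffs.append(abs(got - truth))
            errs[interval] = np.mean(diffs)
        assert errs[5.0] < errs[60.0]
        assert errs[5.0] < 0.25  # within a quarter hour at 5-min sampling

    def test_truth_frame_covers_every_stay(self, small_cohort):
        tables, truth = small_cohort
        assert set(truth["stay_id"]) == set(tables["stays"]["stay_id"])
        for thr in (55, 60, 65, 75, 80):
            assert (truth[f"true_longest_{thr}"] >= 0).all()
        # deaths table agrees with truth's planted outcomes
        dead = set(tables["deaths"]["stay_id"])
        assert set(truth[truth["icu_death"]]["stay_id"]) <= dead

    def test_events_inside_owning_stay(self, small_cohort):
        tables, _ = small_cohort
        from hypoburden.pipeline import validate_inputs
        findings = validate_inputs(tables)
        assert not [f for f in findings if f["level"] == "error"]
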