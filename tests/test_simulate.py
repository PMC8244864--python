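"""Synthetic-study generators: planted truth must be exactly recoverable."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from nestdecay.climate import storm_days, validate_climate
from nestdecay.coding import category_frequencies
from nestdecay.core import compute_ages
from nestdecay.simulate import (ClimateSimConfig, CohortSimConfig,
                                simulate_climate, simulate_cohort,
                                _expected_observed_age)
from nestdecay.survival import ModelSpec, log_likelihood


class TestSimulateClimate:
    def test_planted_storms_recovered_exactly(self, daily_climate):
        detected = storm_days(daily_climate)
        planted = daily_climate["planted_storm"].astype(int)
        assert (detected.to_numpy() == planted.to_numpy()).all()
        assert detected.sum() > 0

    def test_output_is_schema_valid(self, daily_climate):
        validate_climate(daily_climate)

    def test_zero_storm_probability(self):
        cfg = ClimateSimConfig(end=dt.date(2016, 12, 31),
                               storm_prob=(0.0,) * 12, seed=3)
        clim = simulate_climate(cfg)
        assert storm_days(clim).sum() == 0

    def test_bit_reproducible(self):
        cfg = ClimateSimConfig(end=dt.date(2016, 9, 30), seed=9)
        pd.testing.assert_frame_equal(simulate_climate(cfg),
                                      simulate_climate(cfg))

    def test_dry_season_is_drier(self, daily_climate):
        months = pd.to_datetime(daily_climate["date"]).dt.month
        total = daily_climate["rain_day_mm"] + daily_climate["rain_night_mm"]
        dry = total[months.isin([2, 6, 7])].mean()
        wet = total[months.isin([3, 4, 10, 11])].mean()
        assert dry < wet / 2

    def test_declining_trend_gives_negative_slope(self):
        # 15 years with a 3%/year decline: yearly totals regress downward.
        slopes = []
        for seed in range(3):
            cfg = ClimateSimConfig(start=dt.date(2003, 1, 1),
                                   end=dt.date(2017, 12, 31),
                                   yearly_trend=0.97, seed=seed)
            clim = simulate_climate(cfg)
            years = pd.to_datetime(clim["date"]).dt.year
            totals = (clim["rain_day_mm"] + clim["rain_night_mm"]) \
                .groupby(years).sum()
            slopes.append(np.polyfit(totals.index, totals.to_numpy(), 1)[0])
        assert all(s < 0 for s in slopes)


class TestSimulateCohort:
    def test_bit_reproducible(self):
        cfg = CohortSimConfig(n_groups=10, seed=4)
        r1, d1, t1 = simulate_cohort(cfg)
        r2, d2, t2 = simulate_cohort(cfg)
        assert r1 == r2
        pd.testing.assert_frame_equal(d1, d2)
        np.testing.assert_array_equal(t1["true_age"], t2["true_age"])

    def test_immediate_study_end_censors_everything(self):
        cfg = CohortSimConfig(n_groups=5, start=dt.date(2016, 7, 1),
                              end=dt.date(2016, 7, 11), seed=1)
        records, _, truth = simulate_cohort(cfg)
        assert truth["censored_fraction"] == 1.0
        assert all(r.censored for r in records)

    def test_default_censoring_in_plausible_band(self, small_cohort):
        *_, truth = small_cohort
        assert 0.05 <= truth["censored_fraction"] <= 0.26

    def test_large_theta_shrinks_age_dispersion(self):
        # Homogeneous mu (single inert factor) isolates the gamma noise:
        # Var = mu / theta, so theta 10 vs 0.02 shrinks the SD ~22-fold.
        kw = dict(n_groups=30, model_factors=("C",),
                  coefficients={"C": (0.0, 0.0)}, target_mean_days=100.0,
                  seed=2)
        _, _, t_tight = simulate_cohort(CohortSimConfig(theta=10.0, **kw))
        _, _, t_loose = simulate_cohort(CohortSimConfig(theta=0.02, **kw))
        sd_tight, sd_loose = t_tight["true_age"].std(), \
            t_loose["true_age"].std()
        assert sd_tight == pytest.approx(np.sqrt(100.0 / 10.0), rel=0.3)
        assert sd_loose == pytest.approx(np.sqrt(100.0 / 0.02), rel=0.3)
        assert sd_tight < sd_loose / 5

    def test_ages_consistent_with_visit_discretization(self, small_cohort):
        records, _, ages, truth = small_cohort
        obs = ages.set_index("nest_id")
        for i, rec in enumerate(records):
            if not rec.censored:
                a = truth["true_age"][i]
                got = obs.loc[rec.nest_id, "age_days"]
                assert got == 7 * int(np.ceil(max(1, np.ceil(a)) / 7))

    def test_daily_visits_recover_exact_ages(self):
        cfg = CohortSimConfig(n_groups=10, visit_interval_days=1, seed=6)
        records, _, truth = simulate_cohort(cfg)
        ages = compute_ages(records).set_index("nest_id")
        for i, rec in enumerate(records):
            if not rec.censored:
                assert ages.loc[rec.nest_id, "age_days"] == \
                    max(1, int(np.ceil(truth["true_age"][i])))

    def test_category_frequencies_follow_probabilities(self, small_cohort):
        _, design, _, _ = small_cohort
        freq = category_frequencies(design).set_index(["factor", "category"])
        n = len(design)
        # Dominant categories by construction of the defaults.
        assert freq.loc[("F", 2), "n_nests"] > 0.85 * n
        assert freq.loc[("S", 2), "n_nests"] > 0.5 * n

    def test_true_parameters_beat_perturbed_on_likelihood(self, small_cohort):
        _, design, ages, truth = small_cohort
        spec = ModelSpec(factors=tuple(truth["coefficients"]))
        packed = np.concatenate([np.asarray(truth["coefficients"][f])
                                 for f in spec.factors])
        packed[:spec.levels(spec.factors[0])] += truth["base"]
        ll_true, _ = log_likelihood(packed, truth["theta"], design, ages,
                                    spec)
        rng = np.random.default_rng(0)
        for _ in range(5):
            ll_pert, _ = log_likelihood(packed + rng.normal(0, 0.3,
                                                            packed.size),
                                        truth["theta"], design, ages, spec)
            assert ll_pert < ll_true

    def test_expected_observed_age_matches_monte_carlo(self):
        rng = np.random.default_rng(5)
        mu, theta, iv = np.array([95.0]), 0.02, 7
        draws = rng.gamma(mu[0] * theta, 1 / theta, size=200_000)
        mc = (iv * np.ceil(draws / iv)).mean()
        exact = _expected_observed_age(mu, theta, iv)[0]
        assert exact == pytest.approx(mc, rel=0.005)
        assert exact > mu[0]  # discovery lag biases upward
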