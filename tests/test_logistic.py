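"""Retrospective logistic decay estimator and its experiments."""

import numpy as np
import pandas as pd
import pytest

from nestdecay.core import ValidationError
from nestdecay.logistic import (MethodInvalidError, SeparationError,
                                bootstrap_mean_decay, build_scenario,
                                fit_logistic, mean_decay_from_logistic,
                                mean_decay_numerical, subsample_experiment)


def _ages(rows):
    return pd.DataFrame(rows, columns=["nest_id", "group_id", "age_days",
                                       "censored", "mark_offset_days"])


class TestBuildScenario:
    def _truth(self):
        return _ages([("n1", "g1", 80, False, 0),
                      ("n2", "g1", 40, False, 0),
                      ("n3", "g2", 120, False, 30),
                      ("n4", "g2", 20, False, 30),
                      ("n5", "g3", 100, True, 60)])

    def test_status_from_known_decay(self):
        rng_free = self._truth()
        out = build_scenario(rng_free, "three_months_after_last",
                             seed=0).set_index("nest_id")
        # last marking at offset 60; revisit 91 days later
        assert out.loc["n1", "age_at_revisit"] == 151
        assert out.loc["n1", "status"] == 0      # decayed at 80 < 151
        assert out.loc["n3", "age_at_revisit"] == 121
        assert out.loc["n3", "status"] == 0
        assert out.loc["n5", "status"] == 1      # censored at 100 >= 91

    def test_alive_and_decayed_by_revisit_age(self):
        df = _ages([("a", "g1", 50, False, 0), ("b", "g2", 80, False, 50)])
        out = build_scenario(df, "two_weeks_after_last",
                             seed=0).set_index("nest_id")
        # revisit 14 days after the last marking (offset 50): nest a is then
        # 64 days old and decayed at 50; nest b is 14 days old, still alive.
        assert out.loc["a", "age_at_revisit"] == 64 and \
            out.loc["a", "status"] == 0
        assert out.loc["b", "age_at_revisit"] == 14 and \
            out.loc["b", "status"] == 1

    def test_censored_before_revisit_dropped_with_warning(self):
        df = _ages([("a", "g1", 10, True, 0), ("b", "g1", 200, False, 0),
                    ("c", "g2", 30, False, 0)])
        with pytest.warns(UserWarning, match="censored before"):
            out = build_scenario(df, "three_months_after_last", seed=0)
        assert "a" not in set(out["nest_id"])

    def test_far_revisit_invalid(self):
        df = _ages([(f"n{i}", f"g{i}", 50 + i, False, 0) for i in range(6)])
        with pytest.raises(MethodInvalidError, match="method invalid"):
            build_scenario(df, "three_months_after_last", seed=0)

    def test_random_offsets_shared_within_group(self):
        df = _ages([(f"n{i}", f"g{i % 8}", 150, False, 0)
                    for i in range(24)])
        out = build_scenario(df, "random_7_360", seed=1)
        per_group = out.groupby("group_id")["age_at_revisit"].nunique()
        assert (per_group == 1).all()
        out2 = build_scenario(df, "random_7_360", seed=1)
        pd.testing.assert_frame_equal(out, out2)


class TestFitLogistic:
    def test_symmetric_toy_crosses_at_25(self):
        # Symmetric under (t -> 50 - t, status flip), with overlapping
        # statuses so the ML fit is finite; by symmetry the fitted curve
        # crosses 50% exactly at age 25.
        rec = pd.DataFrame({"nest_id": list("abcdef"),
                            "group_id": list("abcdef"),
                            "age_at_revisit": [10, 20, 30, 40, 18, 32],
                            "status": [1, 1, 0, 0, 0, 1]})
        fit = fit_logistic(rec)
        assert -fit.intercept / fit.slope == pytest.approx(25.0, abs=1e-3)
        assert fit.slope < 0

    def test_age_independent_status_has_no_decay_signal(self):
        ages = np.repeat([10, 20, 30, 40], 2)
        status = np.tile([0, 1], 4)
        rec = pd.DataFrame({"nest_id": [f"n{i}" for i in range(8)],
                            "group_id": "g", "age_at_revisit": ages,
                            "status": status})
        fit = fit_logistic(rec)
        assert abs(fit.slope) < 1e-6
        assert np.isnan(fit.mean_decay)

    def test_duplication_invariance(self):
        rec = pd.DataFrame({"nest_id": list("abcdef"),
                            "group_id": list("abcdef"),
                            "age_at_revisit": [10, 30, 50, 60, 70, 90],
                            "status": [1, 1, 0, 1, 0, 0]})
        f1 = fit_logistic(rec)
        f2 = fit_logistic(pd.concat([rec, rec], ignore_index=True))
        assert f1.intercept == pytest.approx(f2.intercept, abs=1e-6)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-9)

    def test_complete_separation_raises(self):
        rec = pd.DataFrame({"nest_id": list("abcd"), "group_id": list("abcd"),
                            "age_at_revisit": [10, 20, 60, 70],
                            "status": [1, 1, 0, 0]})
        with pytest.raises(SeparationError):
            fit_logistic(rec)

    def test_single_status_invalid(self):
        rec = pd.DataFrame({"nest_id": list("ab"), "group_id": list("ab"),
                            "age_at_revisit": [10, 20], "status": [1, 1]})
        with pytest.raises(MethodInvalidError):
            fit_logistic(rec)


class TestMeanDecay:
    def test_closed_form_example(self):
        assert mean_decay_from_logistic(0.0, -0.1) == \
            pytest.approx(np.log(2) / 0.1)

    def test_halving_slope_doubles_mean(self):
        m1 = mean_decay_from_logistic(0.0, -0.1)
        m2 = mean_decay_from_logistic(0.0, -0.05)
        assert m2 == pytest.approx(2 * m1)

    def test_softplus_asymptote(self):
        # Large intercept: nearly all mass alive until ~a/(-b).
        a, b = 30.0, -0.25
        assert mean_decay_from_logistic(a, b) == pytest.approx(a / 0.25,
                                                               rel=1e-6)

    @pytest.mark.parametrize("a", [-2.0, 0.0, 1.5, 4.0])
    @pytest.mark.parametrize("b", [-0.01, -0.05, -0.2])
    def test_closed_form_matches_quadrature(self, a, b):
        closed = mean_decay_from_logistic(a, b)
        numeric = mean_decay_numerical(a, b)
        assert abs(closed - numeric) < 0.1

    def test_nondecaying_fit_rejected(self):
        with pytest.raises(ValidationError, match="infinite mean"):
            mean_decay_from_logistic(0.0, 0.01)


class TestBootstrap:
    def _records(self, seed=0, n_groups=25, mean=90.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(n_groups):
            for j in range(6):
                decay = rng.gamma(2.0, mean / 2.0)
                revisit = rng.integers(7, 361)
                rows.append({"nest_id": f"g{g}n{j}", "group_id": f"g{g}",
                             "age_at_revisit": revisit,
                             "status": int(revisit <= decay)})
        return pd.DataFrame(rows)

    def test_single_replicate_deterministic(self):
        rec = self._records()
        b1 = bootstrap_mean_decay(rec, n_boot=1, seed=3)
        b2 = bootstrap_mean_decay(rec, n_boot=1, seed=3)
        assert b1["replicates"][0] == b2["replicates"][0]

    def test_identical_groups_zero_width(self):
        one = pd.DataFrame({"nest_id": [f"n{i}" for i in range(6)],
                            "group_id": "g",
                            "age_at_revisit": [30, 60, 90, 120, 150, 180],
                            "status": [1, 0, 1, 1, 0, 0]})
        rec = pd.concat([one.assign(group_id=f"g{k}",
                                    nest_id=one["nest_id"] + str(k))
                         for k in range(8)], ignore_index=True)
        boot = bootstrap_mean_decay(rec, n_boot=20, seed=1)
        assert boot["ci_low"] == pytest.approx(boot["ci_high"])

    def test_estimates_track_truth(self):
        boot = bootstrap_mean_decay(self._records(mean=90.0), n_boot=100,
                                    seed=2)
        assert boot["ci_low"] < 90.0 < boot["ci_high"] or \
            abs(boot["estimate"] - 90.0) < 15


class TestSubsample:
    def test_fraction_one_reproduces_full_estimate(self):
        rec = TestBootstrap()._records()
        full = fit_logistic(rec).mean_decay
        table = subsample_experiment(rec, fractions=(1.0,), n_draws=3,
                                     n_boot=10, seed=0)
        assert len(table) == 1
        assert table.iloc[0]["mean_decay"] == pytest.approx(full)
        assert table.iloc[0]["n_nests"] == len(rec)

    def test_bookkeeping_counts_selected_nests(self):
        rec = TestBootstrap()._records()
        table = subsample_experiment(rec, fractions=(0.5,), n_draws=4,
                                     n_boot=10, seed=0)
        assert (table["n_groups"] == 12).all() or \
            (table["n_groups"] == 13).all()
        assert (table["n_nests"] == table["n_groups"] * 6).all()
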