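from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from metafoot.features import (compare_t50_groups,
                               compare_window_groups, dedup_targeted,
                               filter_features, split_directions)


def feature_frame(rows):
    defaults = {"mz": 200.0, "rt_s": 100.0, "ln_fc": -2.0,
                "p_value": 0.01, "max_intensity": 5e7}
    recs = []
    for i, r in enumerate(rows):
        rec = {"id": f"F{i:03d}", **defaults, **r}
        recs.append(rec)
    return pd.DataFrame(recs)


class TestFilter:
    def test_strict_boundaries(self):
        df = feature_frame([
            {"ln_fc": 1.0},                    # removed: strict >
            {"ln_fc": -1.0},                   # removed: strict >
            {"p_value": 0.05},                 # removed: strict <
            {"max_intensity": 1e7},            # removed: strict >
            {"ln_fc": 1.0001, "p_value": 0.0499,
             "max_intensity": 1.0001e7},       # survives
        ])
        out = filter_features(df)
        assert list(out["id"]) == ["F004"]

    def test_constructed_fixture_counts(self):
        passing = [{"ln_fc": 2.0}, {"ln_fc": -1.5}, {"ln_fc": 3.0},
                   {"ln_fc": -2.5}]
        failing = [{"ln_fc": 0.5}, {"p_value": 0.2},
                   {"max_intensity": 1e6}, {"ln_fc": 0.9},
                   {"p_value": 0.9}, {"max_intensity": 5e6}]
        out = filter_features(feature_frame(passing + failing))
        assert len(out) == 4

    def test_empty_input(self):
        assert filter_features(feature_frame([{}]).iloc[0:0]).empty

    def test_idempotent(self):
        df = feature_frame([{"ln_fc": 2.0}, {"ln_fc": 0.5}])
        once = filter_features(df)
        pd.testing.assert_frame_equal(filter_features(once), once)


class TestDedup:
    targets = pd.DataFrame({"compound": ["a"], "mz": [200.0],
                            "rt_s": [100.0]})

    def test_inclusive_boundary_removed(self):
        df = feature_frame([{"mz": 200.001, "rt_s": 130.0}])
        assert dedup_targeted(df, self.targets).empty

    def test_outside_mz_window_kept(self):
        df = feature_frame([{"mz": 200.002, "rt_s": 100.0}])
        assert len(dedup_targeted(df, self.targets)) == 1

    def test_both_tolerances_required(self):
        df = feature_frame([{"mz": 200.0005, "rt_s": 131.0}])
        assert len(dedup_targeted(df, self.targets)) == 1

    def test_constructed_fixture(self):
        targets = pd.DataFrame({
            "compound": list("abcde"),
            "mz": [100.0, 150.0, 200.0, 250.0, 300.0],
            "rt_s": [60.0, 120.0, 180.0, 240.0, 300.0]})
        rows = [{"mz": 100.0004, "rt_s": 70.0},   # overlaps a
                {"mz": 150.001, "rt_s": 150.0},   # overlaps b
                {"mz": 250.0, "rt_s": 240.0},     # overlaps d
                {"mz": 100.0, "rt_s": 120.0},     # rt off for a
                {"mz": 400.0, "rt_s": 60.0},
                {"mz": 199.99, "rt_s": 180.0},
                {"mz": 301.0, "rt_s": 300.0},
                {"mz": 150.0, "rt_s": 240.0}]
        out = dedup_targeted(feature_frame(rows), targets)
        assert len(out) == 5

    def test_filter_dedup_commute(self):
        df = feature_frame([
            {"mz": 200.0, "rt_s": 100.0, "ln_fc": 2.0},
            {"mz": 400.0, "rt_s": 500.0, "ln_fc": 0.5},
            {"mz": 410.0, "rt_s": 500.0, "ln_fc": -3.0},
        ])
        a = filter_features(dedup_targeted(df, self.targets))
        b = dedup_targeted(filter_features(df), self.targets)
        pd.testing.assert_frame_equal(a, b)


class TestSplitDirections:
    def test_sign_of_ln_fc(self):
        df = feature_frame([{"ln_fc": -2.0}, {"ln_fc": 1.5}])
        out = split_directions(df)
        assert list(out["direction"]) == ["decreasing", "increasing"]

    def test_from_area_course_when_ln_fc_missing(self):
        df = pd.DataFrame({
            "id": ["up", "down"],
            "ln_fc": [np.nan, np.nan],
            "area_0h_r1": [1.0, 8.0],
            "area_17h_r1": [2.0, 4.0],
            "area_24h_r1": [4.0, 1.0],
        })
        out = split_directions(df)
        assert list(out["direction"]) == ["increasing", "decreasing"]

    def test_tie_flagged(self):
        df = feature_frame([{"ln_fc": 0.0}])
        assert split_directions(df)["direction"].iloc[0] == "tie"


def pooled_t_oracle(x, y):
    """Textbook pooled-variance two-sample t computed from first
    principles."""
    n1, n2 = len(x), len(y)
    s2 = (np.sum((x - np.mean(x)) ** 2) + np.sum((y - np.mean(y)) ** 2)) \
        / (n1 + n2 - 2)
    return (np.mean(x) - np.mean(y)) / np.sqrt(s2 * (1 / n1 + 1 / n2))


class TestT50Comparison:
    def test_identical_groups_zero_t(self):
        res = compare_t50_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t_statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["mean_difference"] == 0.0

    def test_structural_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        res = compare_t50_groups(rng.normal(18, 1, 21), rng.normal(20, 1, 15))
        assert res["df"] == 34

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n1, n2 = rng.integers(2, 30, size=2)
            x = rng.normal(18.0, rng.uniform(0.2, 2.0), n1)
            y = rng.normal(20.0, rng.uniform(0.2, 2.0), n2)
            res = compare_t50_groups(x, y)
            assert res["t_statistic"] == pytest.approx(pooled_t_oracle(x, y),
                                                       abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_t50_groups([1.0, 1.0], [1.0, 1.0])


def rank_sum_enumeration_p(x, y):
    """Exact two-sided p by enumerating every assignment of the pooled
    ranks to group 1 (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (len(pooled) + 1) / 2
    ws = [sum(c) for c in combinations(ranks, n1)]
    extreme = sum(abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12 for w in ws)
    return extreme / len(ws)


class TestWindowComparison:
    def test_disjoint_groups_maximal_statistic(self):
        res = compare_window_groups([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        n1, n2 = 3, 3
        assert res["U"] == n1 * n2
        assert res["W"] == n1 * n2 + n1 * (n1 + 1) / 2

    def test_exact_small_sample_matches_enumeration(self):
        """n1 = n2 = 3: p-value equals the 20-assignment permutation
        distribution, for several datasets."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(5.0, 1.0, 3)
            y = rng.normal(6.5, 1.0, 3)
            res = compare_window_groups(x, y)
            assert res["method"] == "exact"
            assert res["p_value"] == pytest.approx(
                rank_sum_enumeration_p(x, y), abs=1e-12)

    def test_identical_groups_null_expectation(self):
        res = compare_window_groups([1.0, 2.0, 3.0, 4.0],
                                    [1.0, 2.0, 3.0, 4.0])
        # with full ties, midranks put W at its null mean n1(n1+n2+1)/2
        assert res["ties"]
        assert res["W"] == pytest.approx(4 * 9 / 2)

    def test_rank_sum_and_u_conventions_consistent(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        res = compare_window_groups(x, y)
        assert res["W"] - res["U"] == 8 * 9 / 2
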