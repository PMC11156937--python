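"""Daily-living %TF machinery: bouts, profiles, FDR, rank tests, group stats."""

from datetime import datetime
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from fogbench.core_io import WalkingBouts
from fogbench.daily import (bky_fdr, class_distribution_comparison,
                            compare_groups_hourly, daily_tf, daytime_vs_night,
                            ensemble_or, expand_bouts, hourly_tf,
                            mann_whitney_u, night_reference,
                            severity_comparison, severity_split,
                            wilcoxon_signed_rank)
from fogbench.errors import UndefinedMetricError, ValidationError

MIDNIGHT = datetime(2024, 3, 4, 0, 0, 0)


class TestExpandBouts:
    def test_interval_arithmetic(self):
        mask = expand_bouts(WalkingBouts([(100, 200)]), pad_s=5.0, n=1000,
                            sampling_rate=100.0)
        assert mask[:700].all() is np.bool_(True)  # [max(0,100-500), 200+500)
        assert not mask[700:].any()

    def test_zero_pad_equals_membership(self):
        bouts = WalkingBouts([(2, 5), (8, 9)])
        np.testing.assert_array_equal(
            expand_bouts(bouts, 0.0, 12, 1.0), bouts.membership(12))

    def test_overlapping_pads_merge(self):
        mask = expand_bouts(WalkingBouts([(10, 12), (14, 16)]), pad_s=2.0,
                            n=30, sampling_rate=1.0)
        assert mask[8:18].all()
        eps = np.diff(np.r_[0, mask.astype(int), 0])
        assert (eps == 1).sum() == 1  # one contiguous run


class TestEnsembleOr:
    def test_pointwise_or(self):
        np.testing.assert_array_equal(
            ensemble_or([np.array([0, 1, 0], bool), np.array([1, 1, 0], bool)]),
            [True, True, False])

    def test_single_member_identity(self):
        a = np.array([1, 0, 1], bool)
        np.testing.assert_array_equal(ensemble_or([a]), a)

    def test_tf_never_decreases_with_members(self, rng):
        for _ in range(50):
            members = [rng.random(200) < 0.1 for _ in range(3)]
            bout = np.ones(200, bool)
            combined = ensemble_or(members)
            tf_or = daily_tf(combined, bout, MIDNIGHT, 1.0)[0]
            for m in members:
                assert tf_or >= daily_tf(m, bout, MIDNIGHT, 1.0)[0] - 1e-12


class TestProfiles:
    def test_hourly_ratio(self):
        n = 86400
        decisions = np.zeros(n, bool)
        bout = np.zeros(n, bool)
        bout[3600:4200] = True          # 600 s of bouts in hour 1
        decisions[3600:3660] = True     # 60 s FOG inside them
        profiles, week = hourly_tf(decisions, bout, MIDNIGHT, 1.0)
        assert profiles[0].tf[1] == pytest.approx(10.0)
        assert np.isnan(profiles[0].tf[2])  # zero bout time -> undefined
        assert week[1] == pytest.approx(10.0)

    def test_daily_equals_bout_weighted_hourly_mean(self, rng):
        n = 2 * 86400
        bout = rng.random(n) < 0.05
        decisions = bout & (rng.random(n) < 0.2)
        profiles, _ = hourly_tf(decisions, bout, MIDNIGHT, 1.0)
        daily = daily_tf(decisions, bout, MIDNIGHT, 1.0)
        for p, d in zip(profiles, daily):
            w = p.bout_seconds
            weighted = np.nansum(np.where(w > 0, p.tf * w, 0.0)) / w.sum()
            assert weighted == pytest.approx(d, abs=1e-9)

    def test_daily_extremes(self):
        bout = np.ones(86400, bool)
        assert daily_tf(np.zeros(86400, bool), bout, MIDNIGHT, 1.0)[0] == 0.0
        assert daily_tf(np.ones(86400, bool), bout, MIDNIGHT, 1.0)[0] == 100.0

    def test_midnight_offset_binning(self):
        # recording starting 23:30 puts its second half-hour into hour 0
        start = datetime(2024, 3, 4, 23, 30, 0)
        bout = np.ones(3600, bool)
        decisions = np.zeros(3600, bool)
        decisions[1800:] = True
        profiles, _ = hourly_tf(decisions, bout, start, 1.0)
        assert profiles[0].tf[23] == pytest.approx(0.0)
        assert profiles[1].tf[0] == pytest.approx(100.0)


class TestNightReference:
    def test_all_zero_nights(self):
        week = np.zeros(24)
        assert night_reference(week) == 0.0

    def test_single_defined_bin(self):
        week = np.full(24, np.nan)
        week[23] = 4.2
        assert night_reference(week) == 4.2

    def test_hand_median(self):
        week = np.full(24, np.nan)
        week[[23, 0, 1]] = [1.0, 3.0, 7.0]
        assert night_reference(week) == 3.0

    def test_no_defined_bins_raises(self):
        week = np.full(24, np.nan)
        week[12] = 5.0  # daytime only
        with pytest.raises(UndefinedMetricError):
            night_reference(week)


def bky_oracle(p, q):
    """Literal two-stage linear step-up: returns the rejection set."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])

    def step_up(level):
        last = -1
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= level * rank / m:
                last = rank
        return set(order[:last]) if last > 0 else set()

    q1 = q / (1 + q)
    r1 = len(step_up(q1))
    if r1 == 0:
        return set()
    if r1 == m:
        return set(range(m))
    return step_up(q1 * m / (m - r1))


class TestBkyFdr:
    def test_single_hypothesis(self):
        rejected, adjusted = bky_fdr([0.01], q=0.05)
        assert rejected[0]  # 0.01 <= 0.05/1.05
        assert adjusted[0] == pytest.approx(0.01 / (1 - 0.01), abs=1e-6)

    def test_all_large(self):
        rejected, _ = bky_fdr([0.9] * 10)
        assert not rejected.any()

    def test_matches_literal_oracle(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 13))
            p = np.round(rng.random(m), 2)  # rounding creates ties
            rejected, _ = bky_fdr(p, q=0.05)
            assert set(np.flatnonzero(rejected)) == bky_oracle(list(p), 0.05)

    def test_adjusted_p_consistent_with_rejection(self, rng):
        for q in (0.01, 0.05, 0.2):
            p = rng.random(10)
            rejected, adjusted = bky_fdr(p, q=q)
            np.testing.assert_array_equal(rejected, adjusted <= q + 1e-9)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bky_fdr([0.5, 1.2])


class TestRankTests:
    def test_mann_whitney_exact_disjoint(self):
        _, p = mann_whitney_u([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)

    def test_mann_whitney_identical_samples(self):
        _, p = mann_whitney_u([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_wilcoxon_exact_ordered_pairs(self):
        a = np.arange(8, dtype=float)
        assert wilcoxon_signed_rank(a, a + 1) == pytest.approx(2 / 256)

    def test_wilcoxon_all_zero_differences(self):
        assert wilcoxon_signed_rank(np.ones(5), np.ones(5)) == 1.0

    def test_wilcoxon_matches_enumeration(self, rng):
        # exact null: P(W+ <= w) by enumerating all 2^n sign patterns
        for _ in range(20):
            n = int(rng.integers(5, 10))
            d = rng.normal(size=n)
            while (d == 0).any() or len(np.unique(np.abs(d))) < n:
                d = rng.normal(size=n)
            ranks = np.argsort(np.argsort(np.abs(d))) + 1
            w_obs = ranks[d > 0].sum()
            dist = np.zeros(1)
            for r in ranks:
                dist = np.r_[dist, dist + r]
            total = 2 ** n
            lo = np.sum(dist <= w_obs) / total
            hi = np.sum(dist >= w_obs) / total
            expected = min(1.0, 2 * min(lo, hi))
            assert wilcoxon_signed_rank(d, np.zeros(n)) == pytest.approx(expected)


class TestGroupComparisons:
    def test_identical_groups_not_significant(self, rng):
        base = rng.random((6, 24)) * 5
        report = compare_groups_hourly(base, base.copy())
        assert not report.rejected.any()
        assert (report.adjusted_p > 0.9).all()

    def test_disjoint_groups_exact_p(self):
        a = np.tile([[1.0], [2], [3], [4]], (1, 24))
        b = np.tile([[5.0], [6], [7], [8]], (1, 24))
        report = compare_groups_hourly(a, b)
        assert report.raw_p == pytest.approx(np.full(24, 2 / 70))

    def test_undefined_hours_skipped(self, rng):
        a = rng.random((4, 24))
        b = rng.random((4, 24))
        a[:, 3] = np.nan
        report = compare_groups_hourly(a, b)
        assert 3 in report.skipped_hours
        assert 3 not in report.hours


class TestDaytimeVsNight:
    def test_identical_columns_null(self):
        week = np.full(24, 2.0)
        report = daytime_vs_night([week.copy() for _ in range(5)])
        assert report.friedman_statistic == 0.0
        assert report.friedman_p == 1.0

    def test_shifted_hour_detected(self, rng):
        profiles = []
        for _ in range(30):
            week = np.abs(rng.normal(1.0, 0.2, 24))
            week[9] += 3.0  # one daytime hour uniformly elevated
            profiles.append(week)
        report = daytime_vs_night(profiles)
        j = report.daytime_hours.index(9)
        assert report.friedman_p < 0.05
        assert report.posthoc_adjusted_p[j] < 0.05

    def test_friedman_toy_ranks(self):
        # 3 subjects x (2 daytime hours + night ref): hand rank arithmetic
        profiles = []
        for base in (0.0, 1.0, 2.0):
            week = np.full(24, np.nan)
            week[7], week[8] = base + 2.0, base + 1.0
            week[23] = base  # night reference
            profiles.append(week)
        report = daytime_vs_night(profiles, daytime_hours=(7, 8))
        # ranks identical across subjects (3,2,1): chi2 = 12/(3*3*4)*[...] = 6
        assert report.friedman_statistic == pytest.approx(6.0)


class TestSeverity:
    def test_split_boundary_rule(self):
        manifest = pd.DataFrame({"subject_id": ["a", "b"], "group": ["freezer"] * 2,
                                 "nfogq": [18, 24]})
        out = severity_split(manifest, cutoff=20)
        assert out["moderate"] == ["a"] and out["severe"] == ["b"]

    def test_all_at_cutoff_moderate(self):
        manifest = pd.DataFrame({"subject_id": list("abc"), "group": ["freezer"] * 3,
                                 "nfogq": [20, 20, 20]})
        out = severity_split(manifest)
        assert len(out["moderate"]) == 3 and not out["severe"]

    def test_median_cutoff_counts(self, rng):
        scores = np.r_[rng.integers(10, 21, 25), rng.integers(21, 29, 20)]
        manifest = pd.DataFrame({"subject_id": [f"s{i}" for i in range(45)],
                                 "group": ["freezer"] * 45, "nfogq": scores})
        out = severity_split(manifest, cutoff=20)
        assert len(out["moderate"]) == 25 and len(out["severe"]) == 20

    def test_identical_groups_no_rejections(self, rng):
        base = [rng.random(24) + 1 for _ in range(5)]
        report = severity_comparison({"non": base, "moderate": base, "severe": base})
        assert not report.rejected.any()

    def test_ordered_severity_all_pairs_rejected(self, rng):
        groups = {}
        for name, level in (("non", 0.0), ("moderate", 2.0), ("severe", 4.0)):
            groups[name] = [np.abs(rng.normal(level + 1, 0.1, 24)) for _ in range(8)]
        report = severity_comparison(groups)
        assert report.friedman_p < 0.01
        assert report.rejected.all()

    def test_dunn_z_by_hand(self):
        # hours x groups table with a fixed rank pattern in every block
        profiles = {"g1": [np.full(24, 1.0)], "g2": [np.full(24, 2.0)],
                    "g3": [np.full(24, 3.0)]}
        report = severity_comparison(profiles)
        nb, k = 16, 3
        se = np.sqrt(k * (k + 1) / (6 * nb))
        expected = {("g1", "g2"): -1 / se, ("g1", "g3"): -2 / se,
                    ("g2", "g3"): -1 / se}
        for pair, z in zip(report.pairs, report.dunn_z):
            assert z == pytest.approx(expected[pair])


class TestClassDistributionComparison:
    def test_identical_pairs(self):
        shares = pd.DataFrame({"turn": np.full(8, 80.0), "walking": np.full(8, 20.0)})
        out = class_distribution_comparison(shares, shares.copy())
        assert out == {"turn": 1.0, "walking": 1.0}

    def test_strictly_ordered_pairs(self):
        a = pd.DataFrame({"turn": np.arange(8, dtype=float)})
        b = pd.DataFrame({"turn": np.arange(8, dtype=float) + 1})
        out = class_distribution_comparison(a, b)
        assert out["turn"] == pytest.approx(2 / 256)
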