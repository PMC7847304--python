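"""Tests of behavioral measures and rank statistics."""

import numpy as np
import pytest
from scipy import stats

import voleconn as v
from voleconn.behavior import (STUDY_EXCLUSIONS, MannWhitneyResult,
                               behavior_summary, percent_social_time)


class TestPartnerPreferenceIndex:
    def test_basic_proportion(self):
        assert v.partner_preference_index(90, 10) == pytest.approx(0.90)

    def test_equal_times_give_half(self):
        for x in (0.5, 7, 120):
            assert v.partner_preference_index(x, x) == pytest.approx(0.5)

    def test_complementarity(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 100, size=2)
            total = (v.partner_preference_index(a, b)
                     + v.partner_preference_index(b, a))
            assert total == pytest.approx(1.0, abs=1e-15)

    def test_zero_total_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(v.partner_preference_index(0, 0))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            v.partner_preference_index(-1, 5)


class TestHuddleLatency:
    def test_first_qualifying_bout(self):
        assert v.huddle_latency([(300, 1200)]) == pytest.approx(5.0)

    def test_short_first_bout_skipped(self):
        assert v.huddle_latency([(0, 8), (1800, 2700)]) == pytest.approx(30.0)

    def test_just_below_threshold_is_missing(self):
        assert np.isnan(v.huddle_latency([(0, 9.99)]))

    def test_exact_threshold_counts(self):
        assert v.huddle_latency([(60, 70)]) == pytest.approx(1.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            v.huddle_latency([(100, 90)])

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            v.huddle_latency([(0, 50), (40, 120)])


class TestEffectSizeConvention:
    @pytest.mark.parametrize("u,n1,n2,expected", [
        (378, 32, 32, 0.32),   # partner vs stranger proportions
        (121, 16, 16, 0.05),   # male vs female partner preference
        (118, 16, 16, 0.07),   # male vs female stranger preference
        (119, 16, 16, 0.06),   # 48-h vs 72-h test period
    ])
    def test_printed_u_r_pairs_jointly_consistent(self, u, n1, n2, expected):
        # denominator is the number of unique subjects (32), the only
        # convention under which all four printed pairs agree
        assert round(v.u_effect_size(u, n1, n2, n_subjects=32), 2) == expected

    def test_sample_size_denominator_would_fail(self):
        # the n1+n2 denominator reproduces the pooled test but not the
        # sex-split ones, confirming the unique-subject convention
        assert round(v.u_effect_size(378, 32, 32, n_subjects=64), 2) != 0.32


class TestMannWhitney:
    def test_u_matches_scipy(self, rng):
        x = rng.integers(0, 8, size=14).astype(float)
        y = rng.integers(0, 8, size=11).astype(float)
        res = v.mann_whitney_with_effect(x, y, n_subjects=25)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert res.u == pytest.approx(ref.statistic)

    def test_z_without_continuity_matches_scipy_no_cc(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=15)
        res = v.mann_whitney_with_effect(x, y, n_subjects=27)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_samples_null(self):
        x = np.arange(10.0)
        res = v.mann_whitney_with_effect(x, x.copy(), n_subjects=10)
        assert res.u == pytest.approx(50.0)
        assert res.z == 0.0
        assert res.r_effect == 0.0

    def test_rank_statistic_invariant_to_monotone_transform(self, rng):
        x = rng.uniform(0.1, 1, size=9)
        y = rng.uniform(0.1, 1, size=12)
        a = v.mann_whitney_with_effect(x, y, n_subjects=21)
        b = v.mann_whitney_with_effect(np.exp(5 * x), np.exp(5 * y),
                                       n_subjects=21)
        assert a.u == b.u and a.p == b.p and a.r_effect == b.r_effect

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            v.mann_whitney_with_effect([], [1.0], n_subjects=1)


class TestEdgeBehaviorCorrelation:
    @staticmethod
    def _pair_with_exact_r(r, n, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 2))
        x -= x.mean(axis=0)
        q = np.linalg.qr(x)[0]
        target = np.array([[1.0, r], [r, 1.0]])
        data = q @ np.linalg.cholesky(target).T
        return data[:, 0], data[:, 1]

    def test_printed_a_posteriori_correlation(self):
        # r = -0.468 with n = 28 -> t = r sqrt(26)/sqrt(1-r^2) ~ -2.70;
        # the exact two-tailed p at this (rounded) r is 0.0120
        x, y = self._pair_with_exact_r(-0.468, 28)
        r, df, p = v.edge_behavior_correlation(x, y)
        assert r == pytest.approx(-0.468, abs=1e-10)
        assert df == 26
        t = r * np.sqrt(df) / np.sqrt(1 - r ** 2)
        assert t == pytest.approx(-2.70, abs=0.01)
        assert p == pytest.approx(2 * stats.t.sf(2.7005, 26), abs=5e-4)

    def test_pearson_matches_covariance_oracle(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r, df, _ = v.edge_behavior_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_collinear_points_boundary(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        r, df, p = v.edge_behavior_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_complete(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        x2 = x.copy()
        x2[3] = np.nan
        r_full, df_full, _ = v.edge_behavior_correlation(
            np.delete(x, 3), np.delete(y, 3))
        r_nan, df_nan, _ = v.edge_behavior_correlation(x2, y)
        assert r_nan == pytest.approx(r_full)
        assert df_nan == df_full == 7

    def test_spearman_route(self, rng):
        x = rng.normal(size=20)
        r, df, p = v.edge_behavior_correlation(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            v.edge_behavior_correlation(np.ones(6), np.arange(6.0))


class TestCohortManifest:
    def test_study_accounting_gives_90(self):
        m = v.cohort_manifest(32, 3, STUDY_EXCLUSIONS)
        assert m["retained"] == 90
        assert m["per_session"] == {1: 28, 2: 32, 3: 30}

    def test_no_exclusions(self):
        assert v.cohort_manifest(32, 3)["retained"] == 96

    def test_all_excluded(self):
        exc = [(s, k, "x") for s in range(2) for k in (1, 2, 3)]
        assert v.cohort_manifest(2, 3, exc)["retained"] == 0

    def test_duplicates_collapsed(self):
        m = v.cohort_manifest(4, 3, [(0, 1, "a"), (0, 1, "b")])
        assert m["retained"] == 11

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError, match="unknown subject"):
            v.cohort_manifest(4, 3, [(9, 1, "x")])


def test_percent_social_time():
    assert percent_social_time(100, 43.4, 180) == pytest.approx(79.666, abs=1e-3)
    with pytest.raises(ValueError):
        percent_social_time(1, 1, 0)


def test_behavior_summary_on_synthetic_table(null_cohort):
    _, behavior, _ = null_cohort
    out = behavior_summary(behavior)
    assert 0.4 < out["median_partner_proportion"] < 0.8
    assert out["median_partner_proportion"] + \
        out["median_stranger_proportion"] == pytest.approx(1.0)
    assert isinstance(out["partner_vs_stranger"]["r_effect"], float)
    assert 50 < out["mean_percent_social_time"] < 100
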