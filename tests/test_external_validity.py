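import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from raschval import external_validity as ev


class TestEffectSizeConversions:
    def test_published_mann_whitney_chain(self):
        # z = -4.917 with N = 208 + 100; the printed value is 0.583
        d = ev.mannwhitney_d(-4.917, 308)
        assert d == pytest.approx(0.583, abs=1e-3)

    def test_kruskal_chain_closed_form(self):
        # H = 93.0, k = 3, n = 388 via eta2 = (H - k + 1)/(n - k)
        eta2 = ev.kruskal_eta2(93.0, 3, 388)
        d = ev.d_from_eta2(eta2)
        assert d == pytest.approx(1.113, abs=1e-3)

    def test_d_monotone_and_zero_at_origin(self):
        grid = np.linspace(0, 0.99, 200)
        vals = ev.d_from_r(grid)
        assert vals[0] == 0.0
        assert np.all(np.diff(vals) > 0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 0.95))
    def test_d_r_round_trip(self, r):
        d = ev.d_from_r(r)
        back = d / np.sqrt(4 + d**2)
        assert back == pytest.approx(r, rel=1e-9)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(0, 10, 50)
        res = ev.spearman_assoc(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(0)
        res = ev.spearman_assoc(rng.normal(size=10_000),
                                rng.normal(size=10_000))
        assert abs(res.rho) < 0.03

    def test_interpretation_bands(self):
        assert ev.interpret_correlation(0.55) == "strong"
        assert ev.interpret_correlation(-0.35) == "moderate"
        assert ev.interpret_correlation(0.05) == "negligible"

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            res = ev.spearman_assoc(np.ones(10), np.arange(10.0))
        assert np.isnan(res.rho)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6, 8])
        y = np.array([2.0, 3, 4, 5, np.nan, 7, 9])
        res = ev.spearman_assoc(x, y)
        assert res.n == 5


class TestGroupCompare:
    def test_identical_groups_null(self):
        x = np.arange(40.0)
        groups = np.array(["a", "b"] * 20)
        res = ev.group_compare(x, groups)
        # U near n1*n2/2, d near 0
        assert abs(res.statistic - 200) <= 20
        assert res.cohens_d < 0.35

    def test_exact_symmetric_case(self):
        vals = np.concatenate([np.arange(10.0), np.arange(10.0)])
        groups = np.repeat(["a", "b"], 10)
        res = ev.group_compare(vals, groups)
        assert res.statistic == pytest.approx(50.0)  # n1 n2 / 2
        assert res.cohens_d == pytest.approx(0.0, abs=1e-9)

    def test_shift_detected_two_groups(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 150)
        b = rng.normal(1.0, 1, 150)
        res = ev.group_compare(np.concatenate([a, b]),
                               np.repeat(["a", "b"], 150))
        assert res.p < 1e-8
        assert res.cohens_d > 0.5
        assert res.z is not None

    def test_three_groups_with_posthoc(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([
            rng.normal(0, 1, 80), rng.normal(0.8, 1, 80), rng.normal(1.6, 1, 80)
        ])
        groups = np.repeat(["low", "mid", "high"], 80)
        res = ev.group_compare(vals, groups)
        assert res.k == 3
        assert res.p < 1e-8
        assert len(res.posthoc) == 3
        worst = [p for p in res.posthoc if p["pair"] == ("low", "high")][0]
        assert worst["p_bonferroni"] < 0.001

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=90)
        groups = np.repeat(["a", "b", "c"], 30)
        r1 = ev.group_compare(vals, groups)
        perm = {"a": "c", "b": "a", "c": "b"}
        r2 = ev.group_compare(vals, np.array([perm[g] for g in groups]))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.cohens_d == pytest.approx(r2.cohens_d)

    def test_eta2_variant_flag(self):
        assert ev.kruskal_eta2(10.0, 3, 100, variant="simple") == \
            pytest.approx(10.0 / 99)
        with pytest.raises(ValueError):
            ev.kruskal_eta2(10.0, 3, 100, variant="bogus")


class TestNormalityCheck:
    def test_standard_normal_moments(self):
        rng = np.random.default_rng(4)
        rep = ev.normality_check(rng.normal(size=100_000))
        assert abs(rep.skewness) < 0.05
        assert rep.kurtosis == pytest.approx(3.0, abs=0.05)

    def test_exponential_skewness(self):
        rng = np.random.default_rng(5)
        rep = ev.normality_check(rng.exponential(size=100_000))
        assert rep.skewness == pytest.approx(2.0, abs=0.05)

    def test_skewed_measures_rejected_by_shapiro(self):
        rng = np.random.default_rng(6)
        rep = ev.normality_check(rng.gamma(2.0, 1.0, size=1000))
        assert rep.shapiro_p < 0.05

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            ev.normality_check(np.arange(5.0))


class TestClinicalGroupings:
    def test_edss_groups(self):
        g = ev.edss_three_groups(np.array([0, 3.5, 4.0, 5.5, 6.0, 8.0]))
        assert list(g[:2]) == ["EDSS 0-3.5"] * 2
        assert list(g[2:4]) == ["EDSS 4-5.5"] * 2
        assert list(g[4:]) == ["EDSS >=6"] * 2

    def test_abc_groups(self):
        g = ev.abc_faller_groups(np.array([39.9, 40.0]))
        assert g[0].startswith("ABC <40")
        assert g[1].startswith("ABC >=40")
        f = ev.abc_functioning_groups(np.array([49, 50, 80, 81]))
        assert f[0].endswith("(low)")
        assert f[1].endswith("(moderate)")
        assert f[2].endswith("(moderate)")
        assert f[3].endswith("(high)")

    def test_falls_groups(self):
        g = ev.falls_groups(np.array([0, 1, 2]), cut=1)
        assert g[0] == "falls <1"
        assert g[1] == g[2] == "falls >=1"
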