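import itertools

import numpy as np
import pytest
from scipy import stats

from raschval import classical_scaling as cs


def one_factor_ordinal(n, k, loading, seed, cuts=(-1.2, -0.4, 0.4, 1.2)):
    rng = np.random.default_rng(seed)
    f = rng.normal(size=n)
    X = np.empty((n, k), dtype=int)
    for i in range(k):
        z = loading * f + np.sqrt(1 - loading**2) * rng.normal(size=n)
        X[:, i] = np.digitize(z, cuts)
    return X


class TestClassicalItemStats:
    def test_two_identical_items_alpha_one(self):
        x = np.tile(np.array([0, 1, 2, 3, 4, 2, 1, 3])[:, None], (1, 2))
        res = cs.classical_item_stats(x)
        assert res.alpha == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, size=(5000, 6))
        res = cs.classical_item_stats(x)
        assert abs(res.alpha) < 0.05

    def test_alpha_matches_direct_variance_formula(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 5, size=(60, 8))
        k = x.shape[1]
        expected = k / (k - 1) * (
            1 - x.var(axis=0, ddof=1).sum() / x.sum(axis=1).var(ddof=1)
        )
        assert cs.classical_item_stats(x).alpha == pytest.approx(expected)

    def test_zero_variance_item_warns(self):
        x = np.column_stack([np.full(10, 2), np.arange(10) % 5, np.arange(10) % 3])
        with pytest.warns(UserWarning, match="zero variance"):
            res = cs.classical_item_stats(x)
        assert np.isnan(res.item_rest_rho[0])

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cs.classical_item_stats(np.zeros((2, 5)))


class TestMokkenCoefficients:
    def test_perfect_guttman_gives_h_one(self):
        # double-monotone pattern: every item a step function of the person rank
        persons = np.arange(13)
        X = np.column_stack([np.clip(persons - 2 * i, 0, 4) for i in range(3)])
        res = cs.mokken_coefficients(X)
        assert res.H == pytest.approx(1.0)
        assert np.allclose(res.Hj, 1.0)

    def test_brute_force_oracle_on_toy_table(self):
        # oracle: max covariance over all pairings of the two marginals
        X = np.array(
            [
                [0, 1, 2],
                [1, 1, 3],
                [2, 0, 1],
                [3, 2, 4],
                [4, 3, 4],
                [1, 2, 0],
            ]
        )
        res = cs.mokken_coefficients(X)
        for i, j in itertools.combinations(range(3), 2):
            x, y = X[:, i], X[:, j]
            cov = np.cov(x, y, ddof=0)[0, 1]
            covmax = max(
                np.cov(x, np.array(p), ddof=0)[0, 1]
                for p in itertools.permutations(y)
            )
            assert res.Hij[i, j] == pytest.approx(cov / covmax)

    def test_h_bounded_by_one(self, small_fit):
        res = cs.mokken_coefficients(small_fit["values"])
        assert res.H <= 1.0 + 1e-12
        assert np.all(res.Hj <= 1.0 + 1e-12)

    def test_h_at_least_min_hj(self):
        rng = np.random.default_rng(3)
        X = one_factor_ordinal(400, 6, 0.7, seed=3)
        res = cs.mokken_coefficients(X)
        assert res.H >= res.Hj.min() - 1e-12


class TestMokkenAISP:
    def test_strong_items_form_single_scale(self):
        X = one_factor_ordinal(800, 6, 0.8, seed=4)
        partition = cs.mokken_aisp(X)
        assert set(partition) == {1}

    def test_reversed_item_unscalable(self):
        X = one_factor_ordinal(800, 5, 0.8, seed=5)
        X = np.column_stack([X, 4 - X[:, 0]])  # negative Hij with the rest
        partition = cs.mokken_aisp(X)
        assert partition[-1] == 0
        assert set(partition[:-1]) == {1}


class TestPolychoric:
    def test_known_truth(self):
        rng = np.random.default_rng(6)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=5000)
        cuts = [-1.2, -0.4, 0.4, 1.2]
        x = np.digitize(z[:, 0], cuts)
        y = np.digitize(z[:, 1], cuts)
        r = cs._pair_polychoric(x, y)
        assert abs(r - 0.5) < 0.05

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 5, 4000)
        y = rng.integers(0, 5, 4000)
        assert abs(cs._pair_polychoric(x, y)) < 0.05

    def test_matrix_symmetric_unit_diagonal(self):
        X = one_factor_ordinal(300, 4, 0.6, seed=8)
        R = cs.polychoric_matrix(X)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)

    def test_item_exchange_symmetry(self):
        X = one_factor_ordinal(300, 3, 0.6, seed=9)
        R1 = cs.polychoric_matrix(X)
        R2 = cs.polychoric_matrix(X[:, [1, 0, 2]])
        assert R1[0, 1] == pytest.approx(R2[0, 1], abs=1e-9)

    def test_degenerate_item_rejected(self):
        X = np.column_stack([np.zeros(50, dtype=int), np.arange(50) % 5])
        with pytest.raises(ValueError):
            cs.polychoric_matrix(X)


class TestCFA:
    def test_true_one_factor_model_fits(self):
        X = one_factor_ordinal(2000, 8, 0.75, seed=10)
        R = cs.polychoric_matrix(X)
        fit = cs.cfa_onefactor_fit(R, n=2000)
        assert fit.rmsea < 0.06
        assert fit.cfi > 0.95

    def test_model_implied_matrix_gives_zero_srmr(self):
        lam = np.linspace(0.5, 0.85, 6)
        Sigma = np.outer(lam, lam)
        np.fill_diagonal(Sigma, 1.0)
        fit = cs.cfa_onefactor_fit(Sigma, n=500)
        assert fit.srmr == pytest.approx(0.0, abs=1e-5)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-3)

    def test_two_cluster_structure_flagged(self):
        rng = np.random.default_rng(11)
        n = 1500
        f1 = rng.normal(size=n)
        f2 = 0.3 * f1 + np.sqrt(1 - 0.09) * rng.normal(size=n)
        cuts = (-1.2, -0.4, 0.4, 1.2)
        X = np.empty((n, 6), dtype=int)
        for i in range(3):
            z = 0.8 * f1 + 0.6 * rng.normal(size=n)
            X[:, i] = np.digitize(z, cuts)
        for i in range(3, 6):
            z = 0.8 * f2 + 0.6 * rng.normal(size=n)
            X[:, i] = np.digitize(z, cuts)
        R = cs.polychoric_matrix(X)
        fit = cs.cfa_onefactor_fit(R, n=n)
        assert fit.rmsea > 0.06
        within = [(i, j) for (i, j) in fit.flagged_pairs
                  if (i < 3) == (j < 3)]
        assert within

    def test_correlated_pairs_absorb_dependence(self):
        lam = np.full(5, 0.7)
        Sigma = np.outer(lam, lam)
        Sigma[0, 1] = Sigma[1, 0] = Sigma[0, 1] + 0.2
        np.fill_diagonal(Sigma, 1.0)
        base = cs.cfa_onefactor_fit(Sigma, n=800)
        mod = cs.cfa_onefactor_fit(Sigma, n=800, correlated_pairs=[(0, 1)])
        assert mod.srmr < base.srmr
        assert mod.chi2 < base.chi2
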