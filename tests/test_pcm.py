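import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raschval.rasch_core as rc
from raschval.rasch_core import pcm


class TestCategoryProbs:
    def test_uniform_at_zero(self):
        p = rc.pcm_category_probs(0.0, 0.0, np.zeros(4))
        assert np.allclose(p, 0.2)

    def test_dichotomous_midpoint(self):
        p = rc.pcm_category_probs(1.3, 1.3, np.zeros(1))
        assert p[1] == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-8, 8),
        st.floats(-3, 3),
        st.lists(st.floats(-3, 3), min_size=1, max_size=5),
    )
    def test_normalization(self, theta, delta, tau):
        tau = np.array(tau) - np.mean(tau)
        p = rc.pcm_category_probs(theta, delta, tau)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()


class TestCMLEstimation:
    def test_parameter_recovery(self, recovery_fit):
        true, est, _ = recovery_fit
        thr_true = np.concatenate(true.adjacent_thresholds())
        thr_est = np.concatenate(est.adjacent_thresholds())
        rmse = np.sqrt(np.mean((thr_true - thr_est) ** 2))
        assert rmse < 0.15

    def test_row_permutation_invariance(self, small_fit):
        X = small_fit["values"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[0])
        a = rc.estimate_item_parameters(X)
        b = rc.estimate_item_parameters(X[perm])
        assert np.allclose(a.delta, b.delta)
        for ta, tb in zip(a.tau, b.tau):
            assert np.allclose(ta, tb)

    def test_sum_zero_constraints(self, small_fit):
        params = small_fit["params"]
        assert params.delta.sum() == pytest.approx(0.0, abs=1e-8)
        for t in params.tau:
            assert t.sum() == pytest.approx(0.0, abs=1e-8)

    def test_two_item_grid_oracle(self):
        # dichotomous pair: conditional likelihood depends only on
        # d = delta1 (with delta2 = -delta1); brute-force the grid
        rng = np.random.default_rng(5)
        theta = rng.normal(0, 1, 400)
        p1 = 1 / (1 + np.exp(-(theta - 0.6)))
        p2 = 1 / (1 + np.exp(-(theta + 0.6)))
        X = np.column_stack(
            [rng.random(400) < p1, rng.random(400) < p2]
        ).astype(int)
        est = rc.estimate_item_parameters(X, item_max=np.array([1, 1]))

        n10 = int(np.sum((X[:, 0] == 1) & (X[:, 1] == 0)))
        n01 = int(np.sum((X[:, 0] == 0) & (X[:, 1] == 1)))
        grid = np.arange(-3, 3.0001, 0.01)
        # P(pattern 10 | total 1) with delta1 = d, delta2 = -d
        pr = np.exp(-grid) / (np.exp(-grid) + np.exp(grid))
        ll = n10 * np.log(pr) + n01 * np.log(1 - pr)
        best = grid[np.argmax(ll)]
        assert est.delta[0] == pytest.approx(best, abs=0.01)

    def test_three_item_polytomous_grid_oracle(self):
        # exhaustive conditional likelihood on a coarse grid, 3 items x 2 steps
        rng = np.random.default_rng(6)
        theta = rng.normal(0, 1.2, 500)
        true_beta = [np.array([0.0, -0.4, 0.3]),
                     np.array([0.0, 0.2, 1.0]),
                     np.array([0.0, -0.1, 0.6])]
        X = np.empty((500, 3), dtype=int)
        for i, b in enumerate(true_beta):
            logits = theta[:, None] * np.arange(3)[None, :] - b[None, :]
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            X[:, i] = (rng.random(500)[:, None] > p.cumsum(axis=1)).sum(axis=1)
        est = rc.estimate_item_parameters(X)

        # oracle: direct numerical maximization of the conditional
        # likelihood written from first principles (pattern enumeration)
        from scipy.optimize import minimize

        totals = X.sum(axis=1)
        inner = (totals > 0) & (totals < 6)
        Xi = X[inner]

        patterns = list(itertools.product(range(3), repeat=3))

        def nll(free):
            # free = beta[i][1:], 6 values; gauge: center later
            beta = [np.array([0.0, free[2 * i], free[2 * i + 1]])
                    for i in range(3)]
            eps = [np.exp(-b) for b in beta]
            gamma = np.zeros(7)
            for pat in patterns:
                gamma[sum(pat)] += np.prod([eps[i][pat[i]] for i in range(3)])
            ll = 0.0
            for row in Xi:
                num = np.prod([eps[i][row[i]] for i in range(3)])
                ll += np.log(num / gamma[row.sum()])
            return -ll

        x0 = np.zeros(6)
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000})
        beta_hat = [np.array([0.0, res.x[2 * i], res.x[2 * i + 1]])
                    for i in range(3)]
        oracle = pcm.ItemParameters.from_beta(beta_hat)
        shift = oracle.delta.mean()
        oracle_delta = oracle.delta - shift
        assert np.allclose(est.delta, oracle_delta, atol=0.01)

    def test_null_category_collapsed_with_warning(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 5, size=(200, 3))
        X[:, 0][X[:, 0] == 2] = 1  # category 2 never observed
        with pytest.warns(UserWarning, match="collapsed"):
            params = rc.estimate_item_parameters(X)
        assert params.score_maps is not None
        assert params.item_max[0] == 3

    def test_single_category_item_rejected(self):
        X = np.column_stack([np.full(50, 3), np.arange(50) % 5])
        with pytest.raises(ValueError):
            rc.estimate_item_parameters(X)


class TestPersonMeasures:
    def test_sufficiency(self, small_fit):
        persons = small_fit["persons"]
        by_raw = {}
        for p in persons:
            by_raw.setdefault(p.raw, set()).add(p.theta)
        assert all(len(v) == 1 for v in by_raw.values())

    def test_monotone_in_raw(self, small_fit):
        persons = small_fit["persons"]
        pairs = sorted({(p.raw, p.theta) for p in persons})
        thetas = [t for _, t in pairs]
        assert all(a < b for a, b in zip(thetas, thetas[1:]))

    def test_grid_oracle(self, small_fit):
        params = small_fit["params"]
        X = small_fit["values"][:3]
        persons = rc.estimate_person_measures(X, params)
        grid = np.arange(-8, 8, 0.001)
        for row, est in zip(X, persons):
            ll = np.zeros_like(grid)
            for i in range(params.n_items):
                b = params.beta()[i]
                logits = grid[:, None] * np.arange(len(b))[None, :] - b[None, :]
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                ll += np.log(p[:, row[i]])
            assert est.theta == pytest.approx(grid[np.argmax(ll)], abs=0.005)

    def test_extreme_scores_flagged(self, small_fit):
        params = small_fit["params"]
        X = np.vstack([np.zeros(params.n_items, int),
                       params.item_max[None, :]])
        persons = rc.estimate_person_measures(X, params)
        assert persons[0].extreme and persons[1].extreme
        assert np.isfinite(persons[0].theta) and np.isfinite(persons[1].theta)
        assert persons[0].theta < persons[1].theta

    def test_positive_se(self, small_fit):
        assert all(p.se > 0 for p in small_fit["persons"])


class TestScoreConversion:
    def test_strictly_increasing(self, small_fit):
        table = rc.score_conversion_table(small_fit["params"])
        assert table["theta"].is_monotonic_increasing
        assert (table["theta"].diff().dropna() > 0).all()

    def test_rescaled_endpoints(self, small_fit):
        table = rc.score_conversion_table(small_fit["params"])
        assert table["scaled"].iloc[0] == pytest.approx(0.0)
        assert table["scaled"].iloc[-1] == pytest.approx(100.0)

    def test_sufficiency_oracle(self, small_fit):
        params = small_fit["params"]
        table = rc.score_conversion_table(params).set_index("raw")
        X = small_fit["values"]
        persons = rc.estimate_person_measures(X, params)
        for row, est in zip(X, persons):
            assert est.theta == pytest.approx(
                table.loc[int(row.sum()), "theta"], abs=1e-6
            )


class TestAnchoring:
    def test_idempotence(self, small_fit):
        X = small_fit["values"]
        params = small_fit["params"]
        persons, report, reli = rc.anchor_and_refit(X, params)
        base_theta = rc.theta_array(small_fit["persons"])
        assert np.allclose(rc.theta_array(persons), base_theta)

    def test_anchored_parameters_unchanged(self, small_fit):
        X = small_fit["values"]
        params = small_fit["params"]
        before = [t.copy() for t in params.tau]
        rc.anchor_and_refit(X, params)
        for a, b in zip(params.tau, before):
            assert np.array_equal(a, b)

    def test_determinism_across_samples(self, small_fit):
        X = small_fit["values"][:40]
        params = small_fit["params"]
        p1, _, _ = rc.anchor_and_refit(X, params)
        p2, _, _ = rc.anchor_and_refit(X.copy(), params)
        assert np.array_equal(rc.theta_array(p1), rc.theta_array(p2))

    def test_item_count_mismatch_rejected(self, small_fit):
        with pytest.raises(ValueError):
            rc.anchor_and_refit(small_fit["values"][:, :5], small_fit["params"])

    def test_calibration_on_anchor_simulated_data(self, small_fit):
        # confirmation samples drawn from the anchored parameters fit
        import warnings

        from raschval import synthetic_data as sd
        from raschval.io_types import to_response_matrix

        params = small_fit["params"]
        nonsig = 0
        n_runs = 8
        for seed in range(n_runs):
            cfg = sd.SimulationConfig(
                n_patients=288, obs_per_patient_probs=(1, 0, 0),
                seed=900 + seed,
                item_locations=params.delta - params.delta.mean(),
                item_thresholds=[t - t.mean() for t in params.tau],
            )
            X = to_response_matrix(sd.simulate_dataset(cfg)).values
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, report, _ = rc.anchor_and_refit(X, params, 5)
            nonsig += report.total_p >= report.bonferroni_cutoff
        assert nonsig >= n_runs - 1
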