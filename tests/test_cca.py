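import numpy as np
import pytest
from scipy import linalg

import bbspace as b
from bbspace.cca import CCAPowerModel, PowerQuery


def _oracle_canonical_correlations(x, y):
    """Independent oracle: generalized eigenproblem on covariance blocks."""
    xz = (x - x.mean(0)) / x.std(0, ddof=1)
    yz = (y - y.mean(0)) / y.std(0, ddof=1)
    n = x.shape[0]
    sxx = xz.T @ xz / (n - 1)
    syy = yz.T @ yz / (n - 1)
    sxy = xz.T @ yz / (n - 1)
    m = sxy @ np.linalg.solve(syy, sxy.T)
    vals = linalg.eigh(m, sxx, eigvals_only=True)
    k = min(x.shape[1], y.shape[1])
    return np.sqrt(np.clip(np.sort(vals)[::-1][:k], 0, 1))


class TestFitCCA:
    def test_identical_sets_fully_correlated(self, rng):
        x = rng.standard_normal((40, 3))
        sol = b.fit_cca(x, x.copy())
        np.testing.assert_allclose(sol.canonical_correlations, 1.0, atol=1e-8)

    def test_matches_generalized_eigenproblem_oracle(self, rng):
        x = rng.standard_normal((20, 3))
        y = rng.standard_normal((20, 2))
        sol = b.fit_cca(x, y)
        np.testing.assert_allclose(sol.canonical_correlations,
                                   _oracle_canonical_correlations(x, y), atol=1e-8)

    def test_invariance_to_invertible_linear_maps(self, rng):
        x = rng.standard_normal((60, 4))
        y = rng.standard_normal((60, 3))
        base = b.fit_cca(x, y).canonical_correlations
        a = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        transformed = b.fit_cca(x @ a, y).canonical_correlations
        np.testing.assert_allclose(transformed, base, atol=1e-8)

    def test_variates_unit_variance_and_matched_correlation(self, rng):
        x = rng.standard_normal((80, 5))
        y = rng.standard_normal((80, 3))
        sol = b.fit_cca(x, y)
        np.testing.assert_allclose(sol.u_scores.var(axis=0, ddof=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(sol.v_scores.var(axis=0, ddof=1), 1.0, atol=1e-8)
        for k in range(sol.n_modes):
            r = np.corrcoef(sol.u_scores[:, k], sol.v_scores[:, k])[0, 1]
            assert r == pytest.approx(sol.canonical_correlations[k], abs=1e-8)
        # latent variates mutually uncorrelated within each set
        uu = np.corrcoef(sol.u_scores.T) - np.eye(sol.n_modes)
        assert np.abs(uu).max() < 1e-8

    def test_underdetermined_fit_rejected(self, rng):
        with pytest.raises(ValueError, match="more subjects"):
            b.fit_cca(rng.standard_normal((20, 15)), rng.standard_normal((20, 10)))


class TestModeSignificance:
    def test_planted_strong_mode_hits_floor(self, rng):
        n, n_perm = 1000, 500
        shared = rng.standard_normal(n)
        x = np.outer(shared, rng.standard_normal(6)) + rng.standard_normal((n, 6))
        y = np.outer(shared, rng.standard_normal(3)) + rng.standard_normal((n, 3))
        sol = b.mode_significance(x, y, n_perm=n_perm, seed=0)
        assert sol.mode_pvalues[0] == pytest.approx(1 / (1 + n_perm))
        assert sol.fdr_significant[0]

    def test_pvalues_compatible_with_bh_flags(self, rng):
        sol = b.mode_significance(rng.standard_normal((60, 5)),
                                  rng.standard_normal((60, 3)), n_perm=500, seed=1)
        assert ((sol.mode_pvalues > 0) & (sol.mode_pvalues <= 1)).all()
        if sol.fdr_significant.any():
            assert sol.mode_pvalues[sol.fdr_significant].max() \
                <= sol.mode_pvalues[~sol.fdr_significant].min()


class TestVarianceExplained:
    def test_identical_sets_explain_everything(self, rng):
        x = rng.standard_normal((50, 4))
        sol = b.fit_cca(x, x.copy())
        _, total = b.variance_explained(sol, x)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_independent_sets_explain_almost_nothing(self, rng):
        x = rng.standard_normal((5000, 4))
        y = rng.standard_normal((5000, 3))
        props, _ = b.variance_explained(b.fit_cca(x, y), y)
        assert (props < 0.02).all()

    def test_hand_computed_two_feature_example(self, rng):
        x = rng.standard_normal((200, 2))
        y = rng.standard_normal((200, 2))
        sol = b.fit_cca(x, y)
        props, total = b.variance_explained(sol, y)
        yc = y - y.mean(0)
        var = yc.var(axis=0, ddof=1)
        for k in range(2):
            r2 = np.array([np.corrcoef(yc[:, j], sol.v_scores[:, k])[0, 1] ** 2
                           for j in range(2)])
            assert props[k] == pytest.approx((r2 * var).sum() / var.sum(), abs=1e-10)
        assert total == pytest.approx(props.sum())


class TestProjectItemLoadings:
    def test_identity_transformation_returns_loadings(self, rng):
        load = rng.standard_normal((36, 5))
        np.testing.assert_array_equal(b.project_item_loadings(np.eye(5), load), load)

    def test_matches_bruteforce_product(self, rng):
        psi = rng.standard_normal((5, 5))
        load = rng.standard_normal((36, 5))
        expected = np.array([[load[i] @ psi[:, m] for m in range(5)] for i in range(36)])
        np.testing.assert_allclose(b.project_item_loadings(psi, load), expected, atol=1e-12)
        assert b.project_item_loadings(psi, load).shape == (36, 5)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="inner dimensions"):
            b.project_item_loadings(rng.standard_normal((4, 5)),
                                    rng.standard_normal((36, 5)))


class TestLOOLatentPrediction:
    def test_recovers_planted_shared_latent(self, rng):
        n = 2000
        shared = rng.standard_normal(n)
        wx = rng.standard_normal(10)
        wy = rng.standard_normal(5)
        scale = 1.0  # readout SNR 1 per side => population canonical r = 0.5
        x = scale * np.outer(shared, wx / np.linalg.norm(wx)) + rng.standard_normal((n, 10))
        y = scale * np.outer(shared, wy / np.linalg.norm(wy)) + rng.standard_normal((n, 5))
        true_r = scale**2 / (scale**2 + 1)  # corr of the two optimal readouts
        pred = b.loo_latent_prediction(x, y)
        assert pred[0] == pytest.approx(true_r, abs=0.05)

    def test_overfit_collapse_near_feature_count(self):
        vals = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            vals.append(b.loo_latent_prediction(
                r.standard_normal((60, 20)), r.standard_normal((60, 5)))[0])
        assert np.mean(vals) < 0.15

    def test_prediction_length_matches_subjects(self, rng):
        x = rng.standard_normal((50, 4))
        y = rng.standard_normal((50, 3))
        pred = b.loo_latent_prediction(x, y)
        assert pred.shape == (3,)


def test_sample_canonical_correlation_bias_shrinks_with_n():
    """Null canonical correlations are upward-biased at small n for wide
    feature sets, and the bias shrinks monotonically with n."""
    model = CCAPowerModel(180, 5, 0.05, spectrum_decay=0.0, seed=0)
    means = []
    for n in (200, 1000, 5000):
        rng = np.random.default_rng(3)
        r1 = []
        for _ in range(5):
            x, y = model.sample(n, rng)
            r1.append(b.fit_cca(x, y).canonical_correlations[0])
        means.append(np.mean(r1))
    assert means[0] > 0.5  # gross inflation at n barely above p + q
    assert means[0] > means[1] > means[2]


class TestPowerAnalysis:
    def test_small_case_agrees_with_exhaustive_grid_scan(self):
        """p=q=2 at strong true correlation: the required sample size is
        small, and the bisection search returns the same grid point as an
        exhaustive sequential scan of the same candidate grid."""
        query = PowerQuery(2, 2, 0.9, n_reps=50, n_perm=100, seed=1)
        n_req = b.required_sample_size(query)
        assert n_req <= 100
        model = CCAPowerModel(2, 2, 0.9, query.spectrum_decay, seed=query.seed)
        grid = [32]
        while grid[-1] < 65536:
            grid.append(int(np.ceil(grid[-1] * 1.25)))
        first_pass = None
        for n in grid:
            rng = np.random.default_rng(
                np.random.SeedSequence((query.seed, n)).generate_state(1)[0])
            res = model.evaluate(n, query.n_reps, query.n_perm, rng)
            if res["power"] >= 0.9 and max(
                    res["error_association"], res["error_weights"],
                    res["error_scores"], res["error_loadings"]) <= 0.1:
                first_pass = n
                break
        assert n_req == first_pass

    def test_invalid_queries_rejected(self):
        with pytest.raises(ValueError):
            PowerQuery(2, 2, 1.5)
        with pytest.raises(ValueError):
            PowerQuery(1, 2, 0.5)

    def test_unreachable_targets_raise_bracket_error(self):
        query = PowerQuery(4, 4, 0.2, target_error=0.001, n_reps=10,
                           n_perm=50, seed=0)
        with pytest.raises(RuntimeError, match="bracket"):
            b.required_sample_size(query, n_max=64)
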