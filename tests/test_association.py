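"""Partial correlations, maxT permutation correction, sparse CCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import svd

from roirates import (
    partial_correlation_matrix, permutation_fwe, scca, SparseCCA,
    PartialCorrelationFWE,
)


@pytest.fixture
def gaussian_data(rng):
    n, p, q, k = 40, 6, 5, 2
    cov = rng.normal(size=(n, k))
    X = rng.normal(size=(n, p)) + cov @ rng.normal(size=(k, p))
    Y = rng.normal(size=(n, q)) + cov @ rng.normal(size=(k, q))
    return X, Y, cov


class TestPartialCorrelation:
    def test_self_correlation_diagonal(self, rng):
        X = rng.normal(size=(25, 4))
        r = partial_correlation_matrix(X, X).r.to_numpy()
        np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)
        r_neg = partial_correlation_matrix(X, -X).r.to_numpy()
        np.testing.assert_allclose(np.diag(r_neg), -1.0, atol=1e-12)

    def test_no_covariates_equals_pearson(self, rng):
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 4))
        r = partial_correlation_matrix(X, Y).r.to_numpy()
        oracle = np.corrcoef(X.T, Y.T)[:3, 3:]
        np.testing.assert_allclose(r, oracle, atol=1e-12)

    def test_matches_residualize_then_correlate_oracle(self, gaussian_data):
        """Brute force: statsmodels OLS residuals, then pairwise Pearson."""
        import statsmodels.api as sm

        X, Y, cov = gaussian_data
        r = partial_correlation_matrix(X, Y, covariates=cov).r.to_numpy()
        design = sm.add_constant(cov)
        for i in range(X.shape[1]):
            rx = sm.OLS(X[:, i], design).fit().resid
            for j in range(Y.shape[1]):
                ry = sm.OLS(Y[:, j], design).fit().resid
                oracle = np.corrcoef(rx, ry)[0, 1]
                assert r[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_pingouin(self, gaussian_data):
        import pingouin as pg

        X, Y, cov = gaussian_data
        r = partial_correlation_matrix(X, Y, covariates=cov).r
        df = pd.DataFrame({"x": X[:, 0], "y": Y[:, 0],
                           "c1": cov[:, 0], "c2": cov[:, 1]})
        expected = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])["r"].iloc[0]
        assert r.iloc[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_constant_column_flagged_not_zeroed(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 2.0
        with pytest.warns(RuntimeWarning, match="constant"):
            r = partial_correlation_matrix(X, X).r.to_numpy()
        assert np.isnan(r[1]).all()
        assert np.isfinite(r[0, 0])

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            partial_correlation_matrix(rng.normal(size=(3, 2)),
                                       rng.normal(size=(3, 2)),
                                       covariates=rng.normal(size=(3, 2)))


class TestPermutationFWE:
    def test_duplicated_column_hits_p_floor(self, rng):
        n_perm = 200
        X = rng.normal(size=(60, 3))
        Y = rng.normal(size=(60, 3))
        Y[:, 0] = X[:, 2]
        res = permutation_fwe(X, Y, n_permutations=n_perm, seed=1)
        assert res.p_adjusted.iloc[2, 0] == pytest.approx(1.0 / (n_perm + 1))

    def test_adjusted_geq_unadjusted(self, gaussian_data):
        X, Y, cov = gaussian_data
        res = permutation_fwe(X, Y, covariates=cov, n_permutations=300, seed=2)
        assert (res.p_adjusted.to_numpy() >= res.p_unadjusted.to_numpy() - 1e-12).all()
        assert res.p_adjusted.to_numpy().min() >= 1.0 / 301

    def test_observed_r_matches_partial_correlation(self, gaussian_data):
        X, Y, cov = gaussian_data
        res = permutation_fwe(X, Y, covariates=cov, n_permutations=100, seed=0)
        plain = partial_correlation_matrix(X, Y, covariates=cov)
        np.testing.assert_allclose(res.r.to_numpy(), plain.r.to_numpy(), atol=1e-12)

    def test_too_few_subjects_for_permutations(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="distinct permutations"):
            permutation_fwe(X, X, n_permutations=100, seed=0)

    def test_estimator_facade(self, gaussian_data):
        X, Y, cov = gaussian_data
        est = PartialCorrelationFWE(covariates=cov, n_permutations=150,
                                    random_state=3).fit(X, Y)
        assert est.r_.shape == (X.shape[1], Y.shape[1])
        assert est.p_adjusted_.to_numpy().min() >= 1.0 / 151


class TestSparseCCA:
    def test_penalty_one_matches_svd(self, rng):
        """With inactive constraints the first pair is the leading singular
        pair of the standardized cross-covariance."""
        n, p, q = 60, 7, 5
        X = rng.normal(size=(n, p))
        Y = 0.5 * X[:, :q] + rng.normal(size=(n, q))
        est = SparseCCA(penalty_x=1.0, penalty_y=1.0, n_components=1).fit(X, Y)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        U, s, Vt = svd(Xs.T @ Ys / (n - 1))
        u, v = U[:, 0], Vt[0]
        if np.sign(u[np.argmax(np.abs(u))]) < 0:
            u, v = -u, -v
        np.testing.assert_allclose(est.u_[:, 0], u, atol=1e-8)
        np.testing.assert_allclose(est.v_[:, 0], v, atol=1e-8)
        oracle_cor = np.corrcoef(Xs @ u, Ys @ v)[0, 1]
        assert est.correlations_[0] == pytest.approx(oracle_cor, abs=1e-8)

    def test_rank_one_sparse_recovery(self):
        a = np.zeros(8); a[2] = 3.0; a[5] = -4.0
        b = np.zeros(6); b[1] = 1.0; b[4] = 2.0
        Z = np.outer(a, b)
        from roirates.association import _l1_projected
        u = _l1_projected(Z @ (b / np.linalg.norm(b)), 0.5 * np.sqrt(8))
        np.testing.assert_allclose(np.abs(u), np.abs(a) / np.linalg.norm(a), atol=1e-10)

    def test_sparsity_monotone_in_penalty(self, rng):
        n, p, q = 50, 10, 10
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, q))
        Y[:, :3] += X[:, :3]
        nnz = []
        for pen in (1.0, 0.7, 0.45, 0.25):
            est = SparseCCA(penalty_x=pen, penalty_y=pen, n_components=1).fit(X, Y)
            nnz.append(int((np.abs(est.u_[:, 0]) > 1e-10).sum()
                           + (np.abs(est.v_[:, 0]) > 1e-10).sum()))
        assert nnz == sorted(nnz, reverse=True)

    def test_constraints_hold_post_hoc(self, rng):
        n, p, q = 40, 12, 9
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, q))
        est = SparseCCA(penalty_x=0.2, penalty_y=0.2, n_components=2).fit(X, Y)
        for k in range(2):
            for w, dim, pen in ((est.u_[:, k], p, 0.2), (est.v_[:, k], q, 0.2)):
                assert np.linalg.norm(w) <= 1.0 + 1e-8
                assert np.abs(w).sum() <= max(1.0, pen * np.sqrt(dim)) + 1e-8
                assert np.abs(w).max() > 0

    def test_sign_convention(self, rng):
        X = rng.normal(size=(30, 5))
        Y = rng.normal(size=(30, 5))
        est = SparseCCA(penalty_x=0.6, penalty_y=0.6, n_components=2).fit(X, Y)
        for k in range(2):
            u = est.u_[:, k]
            assert u[np.argmax(np.abs(u))] > 0

    def test_functional_wrapper_returns_pairs(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
        Y = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        pairs = scca(X, Y, n_components=2)
        assert len(pairs) == 2
        assert list(pairs[0].u.index) == list("wxyz")
        assert -1.0 <= pairs[0].correlation <= 1.0

    def test_invalid_penalty(self, rng):
        with pytest.raises(ValueError, match="penalt"):
            SparseCCA(penalty_x=0.0).fit(rng.normal(size=(10, 3)),
                                         rng.normal(size=(10, 3)))
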