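"""Cross-modal association analyses.

Two engines operating on subjects x ROIs matrices (e.g. baseline tau SUVR
against annualized tau change, or baseline volume against annualized
log-Jacobians):

* partial Pearson correlation matrices with max-statistic permutation
  family-wise error correction (maxT): both matrices are residualized on
  the covariates (with intercept), the observed |r| matrix is compared to
  the permutation distribution of the maximum |r| over the whole matrix
  under row permutations of the residualized second dataset
  (Freedman-Lane style, so covariate structure is preserved);

* sparse canonical correlation analysis via penalized matrix decomposition:
  rank-one terms of the cross-covariance are found by alternating
  soft-thresholded power iterations under the constraints ||u||_2 <= 1 and
  ||u||_1 <= penalty * sqrt(dim), with the threshold located by bisection
  and subsequent components obtained by deflation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import svd
from sklearn.base import BaseEstimator

__all__ = [
    "AssociationResult", "CanonicalPair",
    "partial_correlation_matrix", "permutation_fwe",
    "SparseCCA", "scca", "PartialCorrelationFWE",
]


@dataclass
class AssociationResult:
    """Partial-correlation matrix with optional FWE-adjusted p-values."""

    r: pd.DataFrame
    p_adjusted: pd.DataFrame | None = None
    p_unadjusted: pd.DataFrame | None = None
    n_permutations: int = 0
    covariates: list = field(default_factory=list)


def _residualize(M: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of each column after OLS on covariates plus intercept."""
    n = M.shape[0]
    design = np.ones((n, 1))
    if covariates is not None and covariates.size:
        design = np.column_stack([design, covariates])
    coef, *_ = np.linalg.lstsq(design, M, rcond=None)
    return M - design @ coef


def _standardize_columns(M: np.ndarray, label: str) -> np.ndarray:
    """Center and scale columns to unit norm; constant columns become NaN."""
    M = M - M.mean(axis=0)
    norms = np.linalg.norm(M, axis=0)
    bad = norms < 1e-12 * max(1.0, np.abs(M).max())
    if bad.any():
        warnings.warn(
            f"{label}: {int(bad.sum())} constant column(s) after residualization; "
            "their correlations are undefined (NaN)", RuntimeWarning, stacklevel=3)
    norms = np.where(bad, np.nan, norms)
    return M / norms


def _prepare(X, Y, covariates):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be subjects x ROIs with equal subject counts")
    cov = None
    cov_names: list = []
    if covariates is not None:
        cov_df = pd.DataFrame(covariates)
        cov_names = [str(c) for c in cov_df.columns]
        cov = cov_df.to_numpy(dtype=float)
        if cov.shape[0] != X.shape[0]:
            raise ValueError("covariates must have one row per subject")
    k = 0 if cov is None else cov.shape[1]
    if X.shape[0] < k + 3:
        raise ValueError(f"need at least {k + 3} subjects for {k} covariate(s)")
    return X, Y, cov, cov_names


def partial_correlation_matrix(X, Y, covariates=None,
                               x_names=None, y_names=None) -> AssociationResult:
    """Pearson correlations of covariate-residualized X columns vs Y columns."""
    xn = x_names if x_names is not None else getattr(X, "columns", None)
    yn = y_names if y_names is not None else getattr(Y, "columns", None)
    X, Y, cov, cov_names = _prepare(X, Y, covariates)
    Xs = _standardize_columns(_residualize(X, cov), "X")
    Ys = _standardize_columns(_residualize(Y, cov), "Y")
    r = Xs.T @ Ys
    r = pd.DataFrame(np.clip(r, -1.0, 1.0), index=xn, columns=yn)
    return AssociationResult(r=r, covariates=cov_names)


def permutation_fwe(X, Y, covariates=None, n_permutations: int = 10_000,
                    seed: int | None = None, x_names=None, y_names=None) -> AssociationResult:
    """maxT permutation FWE correction for the partial-correlation matrix.

    For each permutation the rows of the residualized Y are shuffled, the
    full |r| matrix recomputed, and its maximum recorded;
    p_adjusted = (1 + #{perm max >= |r_obs|}) / (n_permutations + 1).
    Element-wise (unadjusted) permutation p-values from the same resamples
    are reported alongside.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    xn = x_names if x_names is not None else getattr(X, "columns", None)
    yn = y_names if y_names is not None else getattr(Y, "columns", None)
    X, Y, cov, cov_names = _prepare(X, Y, covariates)
    n = X.shape[0]
    if math.lgamma(n + 1) < math.log(max(n_permutations, 2)):
        raise ValueError(
            f"{n} subjects admit fewer than {n_permutations} distinct permutations")
    Xs = _standardize_columns(_residualize(X, cov), "X")
    Yr = _residualize(Y, cov)
    Ys = _standardize_columns(Yr, "Y")
    r_obs = np.clip(Xs.T @ Ys, -1.0, 1.0)
    abs_obs = np.abs(r_obs)

    rng = np.random.default_rng(seed)
    max_stats = np.empty(n_permutations)
    exceed = np.zeros_like(abs_obs)
    XsT = Xs.T
    for p in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = np.abs(XsT @ Ys[perm])
        max_stats[p] = np.nanmax(r_perm)
        exceed += r_perm >= abs_obs
    counts = (max_stats[:, None, None] >= abs_obs[None]).sum(axis=0)
    p_adj = (1.0 + counts) / (n_permutations + 1.0)
    p_unadj = (1.0 + exceed) / (n_permutations + 1.0)
    return AssociationResult(
        r=pd.DataFrame(r_obs, index=xn, columns=yn),
        p_adjusted=pd.DataFrame(p_adj, index=xn, columns=yn),
        p_unadjusted=pd.DataFrame(p_unadj, index=xn, columns=yn),
        n_permutations=n_permutations,
        covariates=cov_names,
    )


# ---------------------------------------------------------------------------
# sparse CCA (penalized matrix decomposition)

@dataclass
class CanonicalPair:
    """One sparse canonical component."""

    u: pd.Series
    v: pd.Series
    correlation: float
    penalty_x: float
    penalty_y: float
    converged: bool
    n_iter: int


def _soft_threshold(z: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - delta, 0.0)


def _l1_projected(z: np.ndarray, c: float) -> np.ndarray:
    """Unit-L2 vector prop. to soft(z, delta) with ||.||_1 <= c (binary search).

    delta = 0 when the constraint is inactive; otherwise delta is located
    so the L1 norm meets c with equality.
    """
    nz = np.linalg.norm(z)
    if nz == 0:
        raise ValueError("all-zero update vector (zero cross-covariance)")
    u = z / nz
    if np.abs(u).sum() <= c:
        return u
    lo, hi = 0.0, np.abs(z).max()
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        s = _soft_threshold(z, mid)
        ns = np.linalg.norm(s)
        if ns == 0 or np.abs(s).sum() / ns <= c:
            hi = mid  # overshot (or feasible): bring the threshold down
        else:
            lo = mid
    s = _soft_threshold(z, hi)
    ns = np.linalg.norm(s)
    if ns == 0:
        raise ValueError("L1 constraint infeasible: no threshold yields a nonzero vector")
    return s / ns


def _standardize(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        raise ValueError("constant column: cannot standardize for SCCA")
    return M / sd


class SparseCCA(BaseEstimator):
    """Sparse canonical correlation analysis via penalized matrix decomposition.

    Finds pairs of sparse weight vectors (u, v) maximizing u' X' Y v under
    ||u||_2 <= 1, ||u||_1 <= penalty_x * sqrt(p) (and likewise for v).
    With penalties of 1 the constraints are inactive and the solution is
    the leading singular pair of the cross-covariance.

    Parameters
    ----------
    penalty_x, penalty_y : float in (0, 1]
        Lasso penalty fractions (default 0.2 for both datasets).
    n_components : int
        Number of canonical pairs (deflation).
    tol, max_iter : convergence control for the alternating updates.
    random_state : only used for optional random restarts; the default
        initialization (leading right singular vector) is deterministic.

    Attributes
    ----------
    u_, v_ : (p, k) and (q, k) weight arrays
    correlations_ : (k,) Pearson correlations of the canonical variates
    converged_ : (k,) bool;  n_iter_ : (k,) int
    """

    def __init__(self, penalty_x: float = 0.2, penalty_y: float = 0.2,
                 n_components: int = 2, tol: float = 1e-6, max_iter: int = 200,
                 random_state: int | None = None):
        self.penalty_x = penalty_x
        self.penalty_y = penalty_y
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, Y):
        for pen in (self.penalty_x, self.penalty_y):
            if not 0.0 < pen <= 1.0:
                raise ValueError(f"penalties must be in (0, 1], got {pen}")
        self.x_names_ = list(getattr(X, "columns", range(np.asarray(X).shape[1])))
        self.y_names_ = list(getattr(Y, "columns", range(np.asarray(Y).shape[1])))
        X = _standardize(np.asarray(X, dtype=float))
        Y = _standardize(np.asarray(Y, dtype=float))
        n, p = X.shape
        q = Y.shape[1]
        Z = X.T @ Y / (n - 1)
        if not np.any(Z):
            raise ValueError("zero cross-covariance matrix")
        # L1 budgets; a unit-L2 vector always has L1 >= 1, so budgets below 1
        # are infeasible and are clamped to the single-variable limit.
        cu = max(1.0, self.penalty_x * np.sqrt(p))
        cv = max(1.0, self.penalty_y * np.sqrt(q))

        us, vs, cors, conv, iters = [], [], [], [], []
        for _ in range(self.n_components):
            U, s, Vt = svd(Z, full_matrices=False)
            v = Vt[0]
            u = _l1_projected(Z @ v, cu)
            converged = False
            it = 0
            for it in range(1, self.max_iter + 1):
                u_new = _l1_projected(Z @ v, cu)
                v_new = _l1_projected(Z.T @ u_new, cv)
                du = np.linalg.norm(u_new - u)
                dv = np.linalg.norm(v_new - v)
                u, v = u_new, v_new
                if du < self.tol and dv < self.tol:
                    converged = True
                    break
            if not converged:
                warnings.warn("SCCA alternation did not converge; returning best iterate",
                              RuntimeWarning, stacklevel=2)
            # orient so the largest-magnitude u entry is positive
            pivot = np.argmax(np.abs(u))
            if u[pivot] < 0:
                u, v = -u, -v
            xs = X @ u
            ys = Y @ v
            cor = float(np.corrcoef(xs, ys)[0, 1])
            d = float(u @ Z @ v)
            Z = Z - d * np.outer(u, v)
            us.append(u)
            vs.append(v)
            cors.append(cor)
            conv.append(converged)
            iters.append(it)

        self.u_ = np.column_stack(us)
        self.v_ = np.column_stack(vs)
        self.correlations_ = np.asarray(cors)
        self.converged_ = np.asarray(conv)
        self.n_iter_ = np.asarray(iters)
        return self

    def transform(self, X, Y):
        """Canonical variates (X u, Y v) for standardized inputs."""
        if not hasattr(self, "u_"):
            raise AttributeError("SparseCCA is not fitted")
        return _standardize(np.asarray(X, float)) @ self.u_, \
            _standardize(np.asarray(Y, float)) @ self.v_

    def pairs(self) -> list:
        """Results as a list of :class:`CanonicalPair`."""
        return [
            CanonicalPair(
                u=pd.Series(self.u_[:, k], index=self.x_names_, name=f"u{k + 1}"),
                v=pd.Series(self.v_[:, k], index=self.y_names_, name=f"v{k + 1}"),
                correlation=float(self.correlations_[k]),
                penalty_x=self.penalty_x, penalty_y=self.penalty_y,
                converged=bool(self.converged_[k]), n_iter=int(self.n_iter_[k]),
            )
            for k in range(self.u_.shape[1])
        ]


def scca(X, Y, penalty_x: float = 0.2, penalty_y: float = 0.2,
         n_components: int = 2, seed: int | None = None) -> list:
    """Functional wrapper over :class:`SparseCCA`; returns CanonicalPair list."""
    est = SparseCCA(penalty_x=penalty_x, penalty_y=penalty_y,
                    n_components=n_components, random_state=seed)
    return est.fit(X, Y).pairs()


class PartialCorrelationFWE(BaseEstimator):
    """Estimator facade for the permutation-corrected partial correlations.

    Attributes after ``fit(X, Y)``: ``r_``, ``p_adjusted_``,
    ``p_unadjusted_`` (DataFrames) and ``result_`` (AssociationResult).
    """

    def __init__(self, covariates=None, n_permutations: int = 10_000,
                 random_state: int | None = None):
        self.covariates = covariates
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, Y):
        res = permutation_fwe(X, Y, covariates=self.covariates,
                              n_permutations=self.n_permutations,
                              seed=self.random_state)
        self.result_ = res
        self.r_ = res.r
        self.p_adjusted_ = res.p_adjusted
        self.p_unadjusted_ = res.p_unadjusted
        return self
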