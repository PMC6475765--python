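"""Bayesian hierarchical model of regional annualized biomarker change.

The model: for subject i in diagnostic group g(i) with decade-scaled,
centered baseline age x_i = (age_i - 65) / 10, the observed annualized
change in region r is

    y[i, r] = alpha[g(i), r] + beta[g(i), r] * x_i + eps[i, r]

with eps ~ Normal(0, sigma).  Within each group the regional intercepts
alpha[g, .] ~ Normal(mu_alpha[g], tau_alpha[g]) and the regional per-decade
age effects beta[g, .] ~ Normal(mu_beta[g], tau_beta[g]).  Hypermeans carry
standard-normal priors, hyper-scales and the residual scale half-standard-
normal priors.  The hierarchy shares strength across the 84 regions and
addresses multiplicity without per-region testing.

Sampling is blocked Gibbs: the (alpha, beta) regression blocks and the
hypermeans are conjugate normal updates (vectorized across groups and
regions); the non-conjugate scales (half-normal priors) use univariate
slice sampling.  Chains start from overdispersed draws of the priors with
distinct per-chain seeds spawned from the master seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .simulate import CohortTable

__all__ = [
    "HierarchicalSpec", "ModelDesign", "PosteriorDraws", "HierarchicalChangeModel",
    "build_model_input", "fit_mcmc", "gelman_rubin",
    "pooled_atypical_effect", "relative_to_controls", "summarize_regions",
]

DEFAULT_PROBABILITIES = (0.025, 0.10, 0.50, 0.90, 0.975)


# ---------------------------------------------------------------------------
# specification / design containers

@dataclass
class HierarchicalSpec:
    """MCMC schedule and age coding.

    ``chain_length`` is read as the post-burn-in length by default
    (``chain_length_includes_burn_in=False``): the full-scale schedule of
    200 chains x 80,000 draws thinned to every 40th with 15,000 burn-in then
    retains 200 * 80,000/40 = 400,000 draws, matching the printed posterior
    sample size.  Set the flag to True for the alternative reading in which
    burn-in is part of the 80,000.
    """

    n_chains: int = 4
    chain_length: int = 10_000
    thin: int = 10
    burn_in: int = 2_000
    chain_length_includes_burn_in: bool = False
    age_center: float = 65.0
    age_scale: float = 10.0
    per_region_sigma: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.post_burn_in_length < self.thin:
            raise ValueError("chain too short to retain any draws")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "HierarchicalSpec":
        """Scaled-down schedule for interactive runs (4 x 10,000, thin 10)."""
        return cls(n_chains=4, chain_length=10_000, thin=10, burn_in=2_000,
                   seed=seed, **kw)

    @classmethod
    def full_scale(cls, seed: int = 0, **kw) -> "HierarchicalSpec":
        """Full-scale schedule: 200 chains x 80,000, thin 40, burn-in 15,000."""
        return cls(n_chains=200, chain_length=80_000, thin=40, burn_in=15_000,
                   seed=seed, **kw)

    @property
    def post_burn_in_length(self) -> int:
        if self.chain_length_includes_burn_in:
            return self.chain_length - self.burn_in
        return self.chain_length

    @property
    def n_retained(self) -> int:
        """Total retained draws: n_chains * floor(post-burn-in length / thin)."""
        return self.n_chains * (self.post_burn_in_length // self.thin)


@dataclass
class ModelDesign:
    """Prepared model input: y matrix, covariate x, integer group labels."""

    y: np.ndarray          # (n_subjects, n_rois)
    x: np.ndarray          # (n_subjects,) centered/scaled age
    group_idx: np.ndarray  # (n_subjects,) index into `groups`
    groups: tuple
    rois: tuple

    def __post_init__(self) -> None:
        n, R = self.y.shape
        if self.x.shape != (n,) or self.group_idx.shape != (n,):
            raise ValueError("design arrays are inconsistent")
        if R < 2:
            raise ValueError("need at least 2 ROIs")
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        counts = np.bincount(self.group_idx, minlength=len(self.groups))
        singles = [g for g, c in zip(self.groups, counts) if c < 2]
        if singles:
            raise ValueError(f"degenerate design: fewer than 2 subjects in {singles}")
        if not np.isfinite(self.y).all():
            raise ValueError("y contains non-finite values")


def build_model_input(cohort: CohortTable, changes=None,
                      age_center: float = 65.0, age_scale: float = 10.0) -> ModelDesign:
    """Assemble the (y, x, group) design from a cohort and its change table.

    ``changes`` may be a subjects x ROIs wide frame, a tidy frame with
    columns (subject_id, roi, change), or None to annualize from the cohort
    itself.  Missing subject/ROI cells are reported explicitly.
    """
    info = cohort.subject_info()
    if changes is None:
        wide = cohort.annualized_changes()
    elif isinstance(changes, pd.DataFrame) and {"subject_id", "roi", "change"} <= set(changes.columns):
        wide = changes.pivot(index="subject_id", columns="roi", values="change")
        wide = wide.reindex(index=info.index, columns=cohort.roi_names)
    else:
        wide = pd.DataFrame(changes)
    if wide.isna().any().any():
        offenders = [
            f"{s}/{r}" for s, row in wide.iterrows() for r in wide.columns[row.isna()]
        ]
        raise ValueError(
            f"missing change values for {len(offenders)} subject/ROI cells: "
            + ", ".join(offenders[:10])
            + ("..." if len(offenders) > 10 else "")
        )
    info = info.loc[wide.index]
    groups = tuple(pd.unique(info["group"]))
    gmap = {g: i for i, g in enumerate(groups)}
    return ModelDesign(
        y=wide.to_numpy(dtype=float),
        x=((info["age"].to_numpy(dtype=float) - age_center) / age_scale),
        group_idx=np.array([gmap[g] for g in info["group"]]),
        groups=groups,
        rois=tuple(wide.columns),
    )


# ---------------------------------------------------------------------------
# posterior container

@dataclass
class PosteriorDraws:
    """MCMC output, every array indexed (chain, draw, ...)."""

    alpha: np.ndarray      # (C, D, G, R) regional intercepts, change/yr
    beta: np.ndarray       # (C, D, G, R) regional age effects, change/yr/decade
    mu_alpha: np.ndarray   # (C, D, G)
    tau_alpha: np.ndarray  # (C, D, G)
    mu_beta: np.ndarray    # (C, D, G)
    tau_beta: np.ndarray   # (C, D, G)
    sigma: np.ndarray      # (C, D) shared or (C, D, R) per-region
    groups: tuple
    rois: tuple

    @property
    def n_retained(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def group_index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} not in model groups {self.groups}") from None

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains stacked: (C*D, ...)."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def hyper_rhat(self) -> pd.Series:
        """Gelman-Rubin statistic for every hyperparameter (and sigma)."""
        out = {}
        for name in ("mu_alpha", "tau_alpha", "mu_beta", "tau_beta"):
            arr = getattr(self, name)
            for gi, g in enumerate(self.groups):
                out[f"{name}[{g}]"] = gelman_rubin(arr[:, :, gi])
        sig = self.sigma
        if sig.ndim == 2:
            out["sigma"] = gelman_rubin(sig)
        else:
            for ri, r in enumerate(self.rois):
                out[f"sigma[{r}]"] = gelman_rubin(sig[:, :, ri])
        return pd.Series(out, name="rhat")


# ---------------------------------------------------------------------------
# slice sampler for the half-normal-prior scales

def _slice_positive(logf, x0: float, rng, w: float | None = None,
                    max_steps: int = 200) -> float:
    """One univariate slice-sampling update on (0, inf) (stepping-out).

    The step width adapts to the current state, which suits scale
    parameters whose posteriors live on very different magnitudes.
    """
    tiny = 1e-12
    if w is None:
        w = max(0.5 * x0, 0.01)
    height = logf(x0) - rng.exponential(1.0)
    left = x0 - rng.uniform(0.0, w)
    right = left + w
    steps = max_steps
    while left > tiny and logf(left) > height and steps > 0:
        left -= w
        steps -= 1
    left = max(left, tiny)
    steps = max_steps
    while logf(right) > height and steps > 0:
        right += w
        steps -= 1
    while True:
        x1 = rng.uniform(left, right)
        if logf(x1) > height:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _scale_logpost(scale: float, n: int, ssq: float) -> float:
    """log p(scale | .) for a Normal scale with a half-N(0,1) prior."""
    return -0.5 * scale * scale - n * math.log(scale) - ssq / (2.0 * scale * scale)


# ---------------------------------------------------------------------------
# the Gibbs sampler

def _sufficient_stats(design: ModelDesign):
    G = len(design.groups)
    n_g = np.zeros(G)
    sx = np.zeros(G)
    sxx = np.zeros(G)
    R = design.y.shape[1]
    sy = np.zeros((G, R))
    sxy = np.zeros((G, R))
    syy = np.zeros((G, R))
    for gi in range(G):
        sel = design.group_idx == gi
        xg = design.x[sel]
        yg = design.y[sel]
        n_g[gi] = sel.sum()
        sx[gi] = xg.sum()
        sxx[gi] = (xg * xg).sum()
        sy[gi] = yg.sum(axis=0)
        sxy[gi] = xg @ yg
        syy[gi] = (yg * yg).sum(axis=0)
    return n_g, sx, sxx, sy, sxy, syy


def _run_chain(design: ModelDesign, spec: HierarchicalSpec, seed_seq) -> dict:
    rng = np.random.default_rng(seed_seq)
    G = len(design.groups)
    R = design.y.shape[1]
    n_g, sx, sxx, sy, sxy, syy = _sufficient_stats(design)
    n_col = n_g[:, None]
    sx_col = sx[:, None]
    sxx_col = sxx[:, None]
    n_obs_total = int(n_g.sum()) * R
    n_obs_region = int(n_g.sum())

    # overdispersed initialization from the (hyper)priors
    mu_a = rng.normal(0.0, 1.0, G)
    mu_b = rng.normal(0.0, 1.0, G)
    tau_a = np.abs(rng.normal(0.0, 1.0, G)) + 0.1
    tau_b = np.abs(rng.normal(0.0, 1.0, G)) + 0.1
    if spec.per_region_sigma:
        sigma = np.abs(rng.normal(0.0, 1.0, R)) + 0.1
    else:
        sigma = np.array([np.abs(rng.normal()) + 0.1])
    a = mu_a[:, None] + tau_a[:, None] * rng.normal(size=(G, R))
    b = mu_b[:, None] + tau_b[:, None] * rng.normal(size=(G, R))

    post_len = spec.post_burn_in_length
    n_keep = post_len // spec.thin
    total = spec.burn_in + post_len
    keep = {
        "alpha": np.empty((n_keep, G, R)),
        "beta": np.empty((n_keep, G, R)),
        "mu_alpha": np.empty((n_keep, G)),
        "tau_alpha": np.empty((n_keep, G)),
        "mu_beta": np.empty((n_keep, G)),
        "tau_beta": np.empty((n_keep, G)),
        "sigma": np.empty((n_keep, R) if spec.per_region_sigma else (n_keep,)),
    }

    k = 0
    for it in range(total):
        inv_s2 = 1.0 / (sigma * sigma)       # scalar-like (1,) or (R,)
        inv_ta2 = 1.0 / (tau_a * tau_a)
        inv_tb2 = 1.0 / (tau_b * tau_b)

        # --- conjugate (alpha, beta) regression block, all groups x regions
        A00 = n_col * inv_s2 + inv_ta2[:, None]
        A01 = sx_col * inv_s2
        A11 = sxx_col * inv_s2 + inv_tb2[:, None]
        B0 = sy * inv_s2 + (mu_a * inv_ta2)[:, None]
        B1 = sxy * inv_s2 + (mu_b * inv_tb2)[:, None]
        det = A00 * A11 - A01 * A01
        mean_a = (A11 * B0 - A01 * B1) / det
        mean_b = (A00 * B1 - A01 * B0) / det
        L00 = np.sqrt(A00)
        L10 = A01 / L00
        L11 = np.sqrt(A11 - L10 * L10)
        z0 = rng.normal(size=(G, R))
        z1 = rng.normal(size=(G, R))
        w1 = z1 / L11
        w0 = (z0 - L10 * w1) / L00
        a = mean_a + w0
        b = mean_b + w1

        # --- hypermeans, N(0, 1) prior
        prec = R * inv_ta2 + 1.0
        mu_a = (a.sum(axis=1) * inv_ta2) / prec + rng.normal(size=G) / np.sqrt(prec)
        prec = R * inv_tb2 + 1.0
        mu_b = (b.sum(axis=1) * inv_tb2) / prec + rng.normal(size=G) / np.sqrt(prec)

        # --- hyper-scales, half-N(0, 1) prior (slice)
        for gi in range(G):
            ssq = float(((a[gi] - mu_a[gi]) ** 2).sum())
            tau_a[gi] = _slice_positive(
                lambda t, n=R, s=ssq: _scale_logpost(t, n, s), tau_a[gi], rng)
            ssq = float(((b[gi] - mu_b[gi]) ** 2).sum())
            tau_b[gi] = _slice_positive(
                lambda t, n=R, s=ssq: _scale_logpost(t, n, s), tau_b[gi], rng)

        # --- residual scale, half-N(0, 1) prior (slice)
        rss_gr = (syy - 2.0 * (a * sy + b * sxy)
                  + a * a * n_col + 2.0 * a * b * sx_col + b * b * sxx_col)
        if spec.per_region_sigma:
            rss_r = rss_gr.sum(axis=0)
            for ri in range(R):
                sigma[ri] = _slice_positive(
                    lambda s, n=n_obs_region, q=float(rss_r[ri]): _scale_logpost(s, n, q),
                    sigma[ri], rng)
        else:
            rss = float(rss_gr.sum())
            sigma[0] = _slice_positive(
                lambda s, n=n_obs_total, q=rss: _scale_logpost(s, n, q),
                sigma[0], rng)

        if it >= spec.burn_in and (it - spec.burn_in + 1) % spec.thin == 0:
            keep["alpha"][k] = a
            keep["beta"][k] = b
            keep["mu_alpha"][k] = mu_a
            keep["tau_alpha"][k] = tau_a
            keep["mu_beta"][k] = mu_b
            keep["tau_beta"][k] = tau_b
            keep["sigma"][k] = sigma if spec.per_region_sigma else sigma[0]
            k += 1
    assert k == n_keep
    return keep


def fit_mcmc(spec: HierarchicalSpec, design: ModelDesign) -> PosteriorDraws:
    """Run the blocked Gibbs sampler; returns draws for every parameter.

    Chains are independent, with per-chain seeds spawned deterministically
    from ``spec.seed``.
    """
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
    chains = [_run_chain(design, spec, s) for s in seqs]
    stack = {name: np.stack([c[name] for c in chains]) for name in chains[0]}
    return PosteriorDraws(groups=design.groups, rois=design.rois, **stack)


# ---------------------------------------------------------------------------
# diagnostics and posterior functionals

def gelman_rubin(chains) -> float:
    """Classical potential-scale-reduction factor for one scalar parameter.

    ``chains`` is (n_chains, n_draws).  R-hat = sqrt(((n-1)/n W + B/n) / W)
    with W the mean within-chain variance and B = n var(chain means).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    n = x.shape[1]
    w = x.var(axis=1, ddof=1).mean()
    b = n * x.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def pooled_atypical_effect(draws: PosteriorDraws, n_lpa: int, n_pca: int,
                           lpa: str = "LPA", pca: str = "PCA") -> dict:
    """Sample-size-weighted average of the two patient groups, per draw.

    Returns ``{"alpha": (C, D, R), "beta": (C, D, R)}``.
    """
    if n_lpa + n_pca <= 0:
        raise ValueError("total patient count must be positive")
    gl = draws.group_index(lpa)
    gp = draws.group_index(pca)
    w = n_lpa / (n_lpa + n_pca)
    return {
        "alpha": w * draws.alpha[:, :, gl] + (1 - w) * draws.alpha[:, :, gp],
        "beta": w * draws.beta[:, :, gl] + (1 - w) * draws.beta[:, :, gp],
    }


def relative_to_controls(draws: PosteriorDraws, patient=None, control: str = "CU") -> dict:
    """Posterior contrast patient-minus-control per region, at the age center.

    ``patient`` is a pooled-draws dict from :func:`pooled_atypical_effect`,
    a group name, or None (equal-weight pooling is not implied; None means
    the single non-control group when only two groups exist).
    """
    gc = draws.group_index(control)
    if patient is None:
        others = [g for g in draws.groups if g != control]
        if len(others) != 1:
            raise ValueError("specify `patient` when more than one patient group exists")
        patient = others[0]
    if isinstance(patient, str):
        gi = draws.group_index(patient)
        pa, pb = draws.alpha[:, :, gi], draws.beta[:, :, gi]
    else:
        pa, pb = patient["alpha"], patient["beta"]
    return {
        "alpha": pa - draws.alpha[:, :, gc],
        "beta": pb - draws.beta[:, :, gc],
    }


def summarize_regions(contrast_draws, rois,
                      probabilities=DEFAULT_PROBABILITIES) -> pd.DataFrame:
    """Empirical posterior quantiles per region (median, 80% and 95% bars).

    ``contrast_draws`` is (..., n_rois); leading axes are flattened.
    """
    arr = np.asarray(contrast_draws, dtype=float)
    arr = arr.reshape(-1, arr.shape[-1])
    if arr.shape[0] < 100:
        warnings.warn(
            f"only {arr.shape[0]} retained draws; interval estimates are unstable",
            RuntimeWarning, stacklevel=2)
    qs = np.quantile(arr, probabilities, axis=0)
    out = pd.DataFrame(
        qs.T, index=pd.Index(rois, name="roi"),
        columns=[f"q{100 * p:g}" for p in probabilities],
    )
    return out.rename(columns={"q50": "median"})


# ---------------------------------------------------------------------------
# sklearn-style estimator facade

class HierarchicalChangeModel(BaseEstimator):
    """Hierarchical Bayesian regression of regional annualized change.

    Parameters mirror :class:`HierarchicalSpec`.  ``fit`` takes subject
    covariates ``X`` (a DataFrame with columns ``age`` and ``group``) and
    the subjects x regions annualized-change matrix ``y``.

    Attributes (after ``fit``)
    --------------------------
    draws_ : PosteriorDraws
    rhat_ : pd.Series        R-hat for every hyperparameter and sigma
    groups_, rois_ : tuple
    n_retained_ : int
    summary_ : pd.DataFrame  per-region posterior quantiles of the intercepts
    """

    def __init__(self, n_chains: int = 4, chain_length: int = 10_000,
                 thin: int = 10, burn_in: int = 2_000,
                 chain_length_includes_burn_in: bool = False,
                 age_center: float = 65.0, age_scale: float = 10.0,
                 per_region_sigma: bool = False, random_state: int = 0):
        self.n_chains = n_chains
        self.chain_length = chain_length
        self.thin = thin
        self.burn_in = burn_in
        self.chain_length_includes_burn_in = chain_length_includes_burn_in
        self.age_center = age_center
        self.age_scale = age_scale
        self.per_region_sigma = per_region_sigma
        self.random_state = random_state

    def _spec(self) -> HierarchicalSpec:
        return HierarchicalSpec(
            n_chains=self.n_chains, chain_length=self.chain_length,
            thin=self.thin, burn_in=self.burn_in,
            chain_length_includes_burn_in=self.chain_length_includes_burn_in,
            age_center=self.age_center, age_scale=self.age_scale,
            per_region_sigma=self.per_region_sigma,
            seed=0 if self.random_state is None else int(self.random_state),
        )

    def fit(self, X, y):
        X = pd.DataFrame(X)
        if not {"age", "group"} <= set(X.columns):
            raise ValueError("X must have 'age' and 'group' columns")
        y = pd.DataFrame(y)
        if len(y) != len(X):
            raise ValueError("X and y must have the same number of subjects")
        if y.isna().any().any():
            bad = [f"{s}/{r}" for s, row in y.iterrows() for r in y.columns[row.isna()]]
            raise ValueError(f"missing change values: {', '.join(map(str, bad[:10]))}")
        spec = self._spec()
        groups = tuple(pd.unique(X["group"]))
        gmap = {g: i for i, g in enumerate(groups)}
        design = ModelDesign(
            y=y.to_numpy(dtype=float),
            x=(X["age"].to_numpy(dtype=float) - self.age_center) / self.age_scale,
            group_idx=np.array([gmap[g] for g in X["group"]]),
            groups=groups,
            rois=tuple(str(c) for c in y.columns),
        )
        self.groups_ = groups
        self.rois_ = design.rois
        self.draws_ = fit_mcmc(spec, design)
        self.rhat_ = self.draws_.hyper_rhat()
        self.n_retained_ = self.draws_.n_retained
        self.summary_ = {
            g: summarize_regions(self.draws_.alpha[:, :, gi], design.rois)
            for gi, g in enumerate(groups)
        }
        return self

    def contrast(self, n_lpa: int = 18, n_pca: int = 12, control: str = "CU") -> dict:
        """Pooled patients-minus-controls contrast draws (alpha and beta)."""
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted")
        pooled = pooled_atypical_effect(self.draws_, n_lpa, n_pca)
        return relative_to_controls(self.draws_, pooled, control=control)
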