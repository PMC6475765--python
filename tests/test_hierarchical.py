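"""Hierarchical change model: design building, sampler, diagnostics, summaries."""

import numpy as np
import pandas as pd
import pytest

from roirates import (
    SimulationParams, generate_cohort, GROUPS,
    HierarchicalSpec, HierarchicalChangeModel, ModelDesign,
    build_model_input, fit_mcmc, gelman_rubin,
    pooled_atypical_effect, relative_to_controls, summarize_regions,
)
from roirates.hierarchical import PosteriorDraws


class TestDesign:
    @pytest.mark.parametrize("age, expected", [(65.0, 0.0), (75.0, 1.0), (53.0, -1.2)])
    def test_age_centering_and_decade_scaling(self, small_cohort, age, expected):
        design = build_model_input(small_cohort)
        info = small_cohort.subject_info()
        # recompute one subject's x by hand
        x0 = (info["age"].iloc[0] - 65.0) / 10.0
        assert design.x[0] == pytest.approx(x0)
        assert (age - 65.0) / 10.0 == pytest.approx(expected)

    def test_missing_cells_reported(self, small_cohort):
        changes = small_cohort.annualized_changes().reset_index().melt(
            id_vars="subject_id", var_name="roi", value_name="change")
        changes = changes.iloc[:-2]  # drop two subject/ROI cells
        with pytest.raises(ValueError, match="missing change values"):
            build_model_input(small_cohort, changes)

    def test_single_subject_group_rejected(self):
        y = np.random.default_rng(0).normal(size=(3, 4))
        with pytest.raises(ValueError, match="degenerate"):
            ModelDesign(y=y, x=np.zeros(3), group_idx=np.array([0, 0, 1]),
                        groups=("A", "B"), rois=tuple("abcd"))


class TestGelmanRubin:
    def test_identical_chains_hand_value(self):
        # W = 1, B = 0, n = 3 -> sqrt(2/3)
        r = gelman_rubin([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_separated_chains_diverge(self, rng):
        chains = np.stack([rng.normal(0, 0.01, 500), rng.normal(10, 0.01, 500)])
        assert gelman_rubin(chains) > 10

    def test_stationary_chains_approach_one(self, rng):
        chains = rng.normal(size=(4, 20_000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([[1.0, 2.0]])


def _draws_from(alpha, beta=None, groups=("LPA", "PCA", "CU")):
    alpha = np.asarray(alpha, dtype=float)
    beta = alpha.copy() if beta is None else np.asarray(beta, dtype=float)
    C, D, G, R = alpha.shape
    z = np.zeros((C, D, G))
    return PosteriorDraws(alpha=alpha, beta=beta, mu_alpha=z, tau_alpha=z + 1,
                          mu_beta=z, tau_beta=z + 1, sigma=np.zeros((C, D)),
                          groups=tuple(groups), rois=tuple(f"r{i}" for i in range(R)))


class TestPooling:
    def test_equal_sizes_simple_average(self, rng):
        alpha = rng.normal(size=(2, 50, 3, 4))
        draws = _draws_from(alpha)
        pooled = pooled_atypical_effect(draws, 10, 10)
        expected = 0.5 * (alpha[:, :, 0] + alpha[:, :, 1])
        np.testing.assert_allclose(pooled["alpha"], expected, atol=1e-14)

    def test_zero_weight_leaves_other_group(self, rng):
        alpha = rng.normal(size=(1, 30, 3, 2))
        pooled = pooled_atypical_effect(_draws_from(alpha), 18, 0)
        np.testing.assert_array_equal(pooled["alpha"], alpha[:, :, 0])

    def test_study_sizes_arithmetic(self):
        alpha = np.zeros((1, 1, 3, 1))
        alpha[..., 0, :] = 0.10  # LPA
        alpha[..., 1, :] = 0.05  # PCA
        pooled = pooled_atypical_effect(_draws_from(alpha), 18, 12)
        assert pooled["alpha"][0, 0, 0] == pytest.approx(0.08)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            pooled_atypical_effect(_draws_from(np.zeros((1, 2, 3, 2))), 0, 0)


class TestContrast:
    def test_identical_effects_give_zero(self, rng):
        alpha = np.broadcast_to(rng.normal(size=(2, 40, 1, 5)),
                                (2, 40, 3, 5)).copy()
        contrast = relative_to_controls(_draws_from(alpha), "LPA")
        np.testing.assert_allclose(contrast["alpha"], 0.0, atol=1e-14)

    def test_antisymmetric_under_group_swap(self, rng):
        alpha = rng.normal(size=(1, 60, 3, 3))
        draws = _draws_from(alpha)
        ab = relative_to_controls(draws, "LPA", control="PCA")
        ba = relative_to_controls(draws, "PCA", control="LPA")
        np.testing.assert_allclose(ab["alpha"], -ba["alpha"], atol=1e-14)

    def test_missing_control_group(self, rng):
        draws = _draws_from(rng.normal(size=(1, 5, 2, 2)), groups=("LPA", "PCA"))
        with pytest.raises(KeyError, match="CU"):
            relative_to_controls(draws, "LPA")


class TestSummaries:
    def test_constant_draws_collapse_quantiles(self):
        draws = np.full((2, 200, 3), 0.7)
        s = summarize_regions(draws, ["a", "b", "c"])
        assert (s.to_numpy() == 0.7).all()

    def test_quantile_ordering_invariant(self, rng):
        s = summarize_regions(rng.normal(size=(4, 300, 6)), list("abcdef"))
        arr = s[["q2.5", "q10", "median", "q90", "q97.5"]].to_numpy()
        assert (np.diff(arr, axis=1) >= 0).all()

    def test_matches_sorting_based_quantile_oracle(self, rng):
        """Linear interpolation of order statistics, computed by hand."""
        draws = rng.normal(size=(1, 101, 2))
        s = summarize_regions(draws, ["a", "b"])
        flat = np.sort(draws[0, :, 0])
        for p, col in [(0.025, "q2.5"), (0.10, "q10"), (0.50, "median"),
                       (0.90, "q90"), (0.975, "q97.5")]:
            h = p * (len(flat) - 1)
            lo, frac = int(np.floor(h)), h - np.floor(h)
            oracle = flat[lo] * (1 - frac) + flat[min(lo + 1, len(flat) - 1)] * frac
            assert s.loc["a", col] == pytest.approx(oracle, abs=1e-12)

    def test_few_draws_warns(self, rng):
        with pytest.warns(RuntimeWarning, match="draws"):
            summarize_regions(rng.normal(size=(1, 50, 2)), ["a", "b"])


class TestSampler:
    def test_recovers_alpha_on_nearly_noise_free_data(self):
        """Tight hyperpriors off, tiny residual noise: posterior medians of the
        regional intercepts land within 0.005 of the generating values."""
        params = SimulationParams(
            n_lpa=10, n_pca=8, n_control=12, n_roi=6,
            hyper_sd_intercept={g: 0.0 for g in GROUPS},
            hyper_sd_age={g: 0.0 for g in GROUPS},
            residual_sd=1e-3, seed=2,
        )
        cohort = generate_cohort(params)
        design = build_model_input(cohort)
        spec = HierarchicalSpec(n_chains=2, chain_length=3000, thin=5,
                                burn_in=1000, seed=4)
        draws = fit_mcmc(spec, design)
        med = np.median(draws.flat("alpha"), axis=0)  # (G, R)
        for gi, g in enumerate(design.groups):
            truth = np.array([cohort.truth["alpha"][g][r] for r in design.rois])
            assert np.abs(med[gi] - truth).max() < 0.005

    def test_null_data_concentrates_hypermeans_near_zero(self):
        rng = np.random.default_rng(0)
        n, R = 30, 8
        y = rng.normal(0.0, 1e-3, size=(n, R))
        X = pd.DataFrame({"age": rng.uniform(55, 75, n),
                          "group": ["LPA"] * 15 + ["CU"] * 15})
        model = HierarchicalChangeModel(n_chains=2, chain_length=2000,
                                        thin=5, burn_in=500, random_state=1)
        model.fit(X, y)
        mu = model.draws_.flat("mu_alpha")
        assert np.abs(np.median(mu, axis=0)).max() < 0.01

    def test_retained_draw_bookkeeping(self, small_design):
        spec = HierarchicalSpec(n_chains=3, chain_length=905, thin=10,
                                burn_in=200, seed=0)
        draws = fit_mcmc(spec, small_design)
        assert draws.alpha.shape[:2] == (3, 90)
        assert spec.n_retained == 270 == draws.n_retained

    def test_schedule_readings(self):
        assert HierarchicalSpec.full_scale().n_retained == 400_000
        alt = HierarchicalSpec(n_chains=200, chain_length=80_000, thin=40,
                               burn_in=15_000, chain_length_includes_burn_in=True)
        assert alt.n_retained == 200 * ((80_000 - 15_000) // 40)

    def test_estimator_round_trip_params(self):
        model = HierarchicalChangeModel(n_chains=2, chain_length=100)
        params = model.get_params()
        assert params["n_chains"] == 2
        clone = HierarchicalChangeModel(**params)
        assert clone.get_params() == params
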