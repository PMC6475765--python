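"""End-to-end reproducible pipeline: simulate -> quantify -> fit -> compare -> associate.

A run is driven by one :class:`PipelineConfig` (loadable from YAML) and a
single master seed; each stage draws its randomness from a seed spawned
deterministically from the master via fixed offsets (stage name order).
Every run directory carries a provenance record (config, config hash,
seeds, package version, per-stage wall time) sufficient to re-create any
output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import SimulationParams, CohortTable, generate_cohort, generate_phantom
from .quantify import suvr_table_from_volumes, annualized_suvr_change
from .hierarchical import HierarchicalSpec, build_model_input, fit_mcmc, summarize_regions
from .hierarchical import pooled_atypical_effect, relative_to_controls
from .lobes import lobe_average, comparison_matrix
from .association import permutation_fwe, scca

log = logging.getLogger("roirates")

#: fixed offsets from the master seed, one per randomness consumer
_STAGE_OFFSETS = {"simulate_tau": 0, "simulate_volume": 1, "phantom": 2,
                  "fit_tau": 3, "fit_volume": 4, "associate": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 1_000_003 + _STAGE_OFFSETS[stage]) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    out_dir: str = "runs/demo"
    seed: int = 0
    profile: str = "desk"  # "desk" or "full" MCMC schedule
    modalities: tuple = ("tau", "volume")
    simulation: dict = field(default_factory=dict)       # SimulationParams overrides
    mcmc: dict = field(default_factory=dict)             # HierarchicalSpec overrides
    n_permutations: int = 1_000
    scca_penalty: float = 0.2
    scca_components: int = 2
    stages: tuple = ("simulate", "quantify", "fit", "compare-lobes", "associate")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("modalities", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def simulation_params(self, modality: str) -> SimulationParams:
        # `simulation` is either {modality: {overrides}} or one flat override
        # dict applied to every modality
        if any(m in self.simulation for m in self.modalities):
            overrides = dict(self.simulation.get(modality, {}))
        else:
            overrides = dict(self.simulation)
        params = SimulationParams(modality=modality, **overrides)
        if modality == "volume" and not overrides:
            # annualized percent volume change: negative rates for patients
            params.hyper_mean_intercept = {"LPA": -1.2, "PCA": -1.3, "CU": -0.2}
            params.hyper_sd_intercept = {"LPA": 0.4, "PCA": 0.4, "CU": 0.1}
            params.hyper_mean_age = {"LPA": 0.4, "PCA": 0.4, "CU": 0.0}
            params.hyper_sd_age = {"LPA": 0.15, "PCA": 0.15, "CU": 0.05}
            params.residual_sd = 0.6
            params.baseline_mean = {"LPA": 100.0, "PCA": 100.0, "CU": 100.0}
            params.baseline_sd = 5.0
        params.seed = stage_seed(self.seed, f"simulate_{modality}")
        return params

    def mcmc_spec(self, modality: str) -> HierarchicalSpec:
        base = HierarchicalSpec.full_scale() if self.profile == "full" else HierarchicalSpec.desk()
        spec = HierarchicalSpec(**{**asdict_spec(base), **self.mcmc})
        spec.seed = stage_seed(self.seed, f"fit_{modality}")
        return spec


def asdict_spec(spec: HierarchicalSpec) -> dict:
    return {k: getattr(spec, k) for k in (
        "n_chains", "chain_length", "thin", "burn_in",
        "chain_length_includes_burn_in", "age_center", "age_scale",
        "per_region_sigma")}


def validate_cohort_csv(path) -> CohortTable:
    """Fail fast on malformed cohort tables before any compute."""
    df = pd.read_csv(path)
    missing = [c for c in CohortTable.REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    if (df["interval_days"] <= 0).any():
        raise ValueError(f"cohort file {path} has non-positive scan intervals")
    return CohortTable(data=df)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings: dict = {}
    provenance = {
        "package": "roirates",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_OFFSETS},
        "timings_s": timings,
    }
    try:
        cohorts: dict = {}
        changes: dict = {}
        if "simulate" in config.stages:
            t0 = time.perf_counter()
            cdir = out / "cohort"
            cdir.mkdir(exist_ok=True)
            for modality in config.modalities:
                params = config.simulation_params(modality)
                cohort = generate_cohort(params)
                cohort.write(cdir / f"cohort_{modality}.csv",
                             cdir / f"truth_{modality}.json")
                cohorts[modality] = cohort
                log.info("simulated %s cohort: %d rows", modality, len(cohort.data))
            timings["simulate"] = time.perf_counter() - t0

        if "quantify" in config.stages:
            t0 = time.perf_counter()
            cdir = out / "cohort"
            cdir.mkdir(exist_ok=True)
            for modality in config.modalities:
                if modality not in cohorts:
                    cohorts[modality] = validate_cohort_csv(cdir / f"cohort_{modality}.csv")
                ch = cohorts[modality].annualized_changes()
                ch.to_csv(cdir / f"changes_{modality}.csv")
                changes[modality] = ch
            # phantom demonstration of the image-level quantification path
            rng = np.random.default_rng(stage_seed(config.seed, "phantom"))
            medians = rng.uniform(1.0, 3.0, 84)
            base, follow = generate_phantom(84, medians, reference_median=2.0,
                                            seed=stage_seed(config.seed, "phantom"))
            suvr_b = suvr_table_from_volumes(base.uptake, base.labels,
                                             base.gm_probability, base.reference_label)
            suvr_f = suvr_table_from_volumes(follow.uptake, follow.labels,
                                             follow.gm_probability, follow.reference_label)
            interval = 365.25
            phantom_tbl = pd.DataFrame({
                "suvr_baseline": suvr_b, "suvr_followup": suvr_f,
                "annualized_change": annualized_suvr_change(
                    suvr_b.to_numpy(), suvr_f.to_numpy(), interval),
            })
            phantom_tbl.index.name = "label"
            phantom_tbl.to_csv(cdir / "phantom_suvr.csv")
            timings["quantify"] = time.perf_counter() - t0

        contrasts: dict = {}
        rois_by_modality: dict = {}
        if "fit" in config.stages:
            t0 = time.perf_counter()
            pdir = out / "posterior"
            pdir.mkdir(exist_ok=True)
            for modality in config.modalities:
                cohort = cohorts[modality]
                design = build_model_input(cohort, changes.get(modality))
                spec = config.mcmc_spec(modality)
                draws = fit_mcmc(spec, design)
                pooled = pooled_atypical_effect(
                    draws,
                    n_lpa=int((cohort.subject_info()["group"] == "LPA").sum()),
                    n_pca=int((cohort.subject_info()["group"] == "PCA").sum()))
                contrast = relative_to_controls(draws, pooled)
                contrasts[modality] = contrast
                rois_by_modality[modality] = design.rois
                summarize_regions(contrast["alpha"], design.rois).to_csv(
                    pdir / f"summary_change_{modality}.csv")
                summarize_regions(contrast["beta"], design.rois).to_csv(
                    pdir / f"summary_decade_effect_{modality}.csv")
                rhat = draws.hyper_rhat()
                rhat.to_csv(pdir / f"rhat_{modality}.csv")
                log.info("fitted %s model: %d retained draws, max hyper R-hat %.3f",
                         modality, draws.n_retained, rhat.max())
            timings["fit"] = time.perf_counter() - t0

        if "compare-lobes" in config.stages:
            t0 = time.perf_counter()
            ldir = out / "lobes"
            ldir.mkdir(exist_ok=True)
            for modality, contrast in contrasts.items():
                lobe_map = pd.Series(cohorts[modality].data
                                     .drop_duplicates("roi")
                                     .set_index("roi")["lobe"])
                lobe_draws, lobe_order = lobe_average(
                    contrast["alpha"], rois_by_modality[modality], lobe_map)
                mat = comparison_matrix(lobe_draws, lobe_order)
                mat.to_frame().to_csv(ldir / f"lobe_probabilities_{modality}.csv")
                mat.display().to_csv(ldir / f"lobe_probabilities_{modality}_display.csv")
            timings["compare-lobes"] = time.perf_counter() - t0

        if "associate" in config.stages:
            t0 = time.perf_counter()
            adir = out / "associations"
            adir.mkdir(exist_ok=True)
            pairings = _association_pairings(cohorts, changes, config.modalities)
            for name, Xd, Yd, cov in pairings:
                res = permutation_fwe(Xd, Yd, covariates=cov,
                                      n_permutations=config.n_permutations,
                                      seed=stage_seed(config.seed, "associate"))
                res.r.to_csv(adir / f"r_{name}.csv")
                res.p_adjusted.to_csv(adir / f"p_adjusted_{name}.csv")
                pairs = scca(Xd, Yd, penalty_x=config.scca_penalty,
                             penalty_y=config.scca_penalty,
                             n_components=config.scca_components)
                weights = pd.DataFrame(
                    {f"u{k + 1}": p.u for k, p in enumerate(pairs)}
                    | {f"v{k + 1}": p.v for k, p in enumerate(pairs)})
                weights.to_csv(adir / f"scca_weights_{name}.csv")
                pd.Series({f"component_{k + 1}": p.correlation
                           for k, p in enumerate(pairs)}).to_csv(
                    adir / f"scca_correlations_{name}.csv")
            timings["associate"] = time.perf_counter() - t0

        provenance["status"] = "ok"
    except Exception as exc:
        provenance["status"] = "error"
        provenance["error"] = {"stage": "unknown", "type": type(exc).__name__,
                               "message": str(exc)}
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, default=str)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, default=str)
    return out


def _association_pairings(cohorts, changes, modalities):
    """The four analysis pairings, restricted to available modalities.

    Associations are computed within the patient cohort (LPA + PCA),
    with baseline age as the partialled covariate.
    """
    out = []
    have_tau = "tau" in modalities and "tau" in cohorts
    have_vol = "volume" in modalities and "volume" in cohorts

    def patient_parts(modality):
        cohort = cohorts[modality]
        info = cohort.subject_info()
        patients = info.index[info["group"] != "CU"]
        base = cohort.wide("baseline").loc[patients]
        chg = changes[modality].loc[patients]
        age = info.loc[patients, ["age"]]
        return base, chg, age

    if have_tau:
        tb, tc, age = patient_parts("tau")
        out.append(("baseline_tau_vs_tau_change", tb, tc, age))
    if have_vol:
        vb, vc, age_v = patient_parts("volume")
        out.append(("baseline_volume_vs_jacobian", vb, vc, age_v))
    if have_tau and have_vol:
        common = tb.index.intersection(vb.index)
        out.append(("baseline_tau_vs_jacobian", tb.loc[common], vc.loc[common],
                    age.loc[common]))
        out.append(("tau_change_vs_jacobian", tc.loc[common], vc.loc[common],
                    age.loc[common]))
    return out
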