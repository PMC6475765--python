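"""Synthetic longitudinal ROI cohorts and voxel phantoms.

The simulator is the generative mirror of the hierarchical change model: per
diagnostic group g and region r it draws a regional annualized-change
intercept alpha[g, r] and a regional per-decade age slope beta[g, r] from
group-level normal distributions, gives every subject a true annualized
change alpha + beta * (age - 65) / 10 in each region, and observes the
follow-up value with a single residual noise term.  The drawn regional
effects ("truth") are recorded so downstream estimators can be scored
against known ground truth.

The voxel phantoms exercise the quantification stage: small label volumes
whose tissue-masked ROI medians equal stated targets exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("LPA", "PCA", "CU")

#: Default group-level means/sds of the annualized tau change (SUVR/yr) and
#: of the per-decade age slope.  Patients accumulate tau (positive rates up
#: to ~0.1 SUVR/yr) with a negative age slope (younger patients faster);
#: controls change little.
_DEFAULT_MEAN_INTERCEPT = {"LPA": 0.08, "PCA": 0.07, "CU": 0.01}
_DEFAULT_SD_INTERCEPT = {"LPA": 0.03, "PCA": 0.03, "CU": 0.01}
_DEFAULT_MEAN_AGE = {"LPA": -0.03, "PCA": -0.03, "CU": 0.0}
_DEFAULT_SD_AGE = {"LPA": 0.01, "PCA": 0.01, "CU": 0.005}
_DEFAULT_BASELINE_MEAN = {"LPA": 1.6, "PCA": 1.6, "CU": 1.2}

DAYS_PER_YEAR = 365.25


def default_lobe_map() -> pd.Series:
    """Packaged 84-ROI -> 8-lobe assignment (index roi name, values lobe)."""
    from importlib.resources import files

    path = files("roirates.data").joinpath("lobe_map.csv")
    with path.open() as fh:
        df = pd.read_csv(fh)
    return pd.Series(df["lobe"].to_numpy(), index=df["roi"], name="lobe")


@dataclass
class SimulationParams:
    """Study-condition parameters for the cohort generator.

    Defaults mirror the study cohort: 18 LPA + 12 PCA patients, 45
    cognitively unimpaired controls, 84 cortical/subcortical ROIs in 8
    lobes, baseline ages uniform on 53-80 years, scan intervals uniform on
    348-406 days.
    """

    n_lpa: int = 18
    n_pca: int = 12
    n_control: int = 45
    n_roi: int = 84
    lobe_map: pd.Series | None = None
    hyper_mean_intercept: dict = field(default_factory=lambda: dict(_DEFAULT_MEAN_INTERCEPT))
    hyper_sd_intercept: dict = field(default_factory=lambda: dict(_DEFAULT_SD_INTERCEPT))
    hyper_mean_age: dict = field(default_factory=lambda: dict(_DEFAULT_MEAN_AGE))
    hyper_sd_age: dict = field(default_factory=lambda: dict(_DEFAULT_SD_AGE))
    residual_sd: float = 0.05
    residual_structure: str = "shared"  # or "per_region"
    baseline_mean: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINE_MEAN))
    baseline_sd: float = 0.2
    age_range: tuple = (53.0, 80.0)
    interval_range: tuple = (348.0, 406.0)
    age_center: float = 65.0
    age_scale: float = 10.0
    modality: str = "tau"
    seed: int = 0

    def validate(self) -> None:
        if self.n_roi < 2:
            raise ValueError("n_roi must be >= 2")
        for name in ("hyper_sd_intercept", "hyper_sd_age"):
            d = getattr(self, name)
            for g in GROUPS:
                if g not in d:
                    raise ValueError(f"{name} missing group {g!r}")
                if d[g] < 0:
                    raise ValueError(f"{name}[{g!r}] must be >= 0, got {d[g]}")
        if np.any(np.asarray(self.residual_sd) < 0):
            raise ValueError(f"residual_sd must be >= 0, got {self.residual_sd}")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if self.residual_structure not in ("shared", "per_region"):
            raise ValueError(f"unknown residual_structure {self.residual_structure!r}")
        if not (self.age_range[0] <= self.age_range[1]):
            raise ValueError("age_range must be (min, max)")
        if self.interval_range[0] <= 0:
            raise ValueError("interval_range must be positive")
        if self.lobe_map is not None:
            if len(self.lobe_map) != self.n_roi:
                raise ValueError("lobe_map length must equal n_roi")
            if self.lobe_map.isna().any():
                raise ValueError("every ROI must be mapped to a lobe")

    def resolved_lobe_map(self) -> pd.Series:
        if self.lobe_map is not None:
            return self.lobe_map
        if self.n_roi == 84:
            return default_lobe_map()
        # generic fallback: round-robin over 8 lobes
        lobes = [
            "frontal", "sensorimotor", "medial temporal", "lateral temporal",
            "medial parietal", "lateral parietal", "medial occipital", "lateral occipital",
        ]
        names = [f"roi_{i + 1:03d}" for i in range(self.n_roi)]
        return pd.Series([lobes[i % 8] for i in range(self.n_roi)], index=names, name="lobe")


@dataclass
class CohortTable:
    """Tidy longitudinal table plus the generating ground truth.

    ``data`` has one row per subject x ROI x timepoint with columns
    subject_id, group, age, roi, lobe, modality, timepoint, value,
    interval_days.  ``truth`` records the drawn regional intercepts/slopes.
    """

    data: pd.DataFrame
    truth: dict | None = None

    REQUIRED_COLUMNS = (
        "subject_id", "group", "age", "roi", "lobe", "modality",
        "timepoint", "value", "interval_days",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")

    @property
    def roi_names(self) -> list:
        return list(pd.unique(self.data["roi"]))

    def subject_info(self) -> pd.DataFrame:
        """One row per subject: group, age, interval_days."""
        cols = ["subject_id", "group", "age", "interval_days"]
        return self.data[cols].drop_duplicates("subject_id").set_index("subject_id")

    def wide(self, timepoint: str) -> pd.DataFrame:
        """Subjects x ROIs matrix of values at one timepoint."""
        sub = self.data[self.data["timepoint"] == timepoint]
        wide = sub.pivot(index="subject_id", columns="roi", values="value")
        return wide.loc[:, self.roi_names]

    def annualized_changes(self) -> pd.DataFrame:
        """Subjects x ROIs annualized change (follow-up - baseline) / years."""
        base = self.wide("baseline")
        follow = self.wide("followup").loc[base.index]
        years = self.subject_info().loc[base.index, "interval_days"] / DAYS_PER_YEAR
        return (follow - base).div(years, axis=0)

    def write(self, csv_path, truth_path=None) -> None:
        self.data.to_csv(csv_path, index=False)
        if truth_path is not None and self.truth is not None:
            with open(truth_path, "w") as fh:
                json.dump(self.truth, fh, indent=1)

    @classmethod
    def read(cls, csv_path, truth_path=None) -> "CohortTable":
        data = pd.read_csv(csv_path)
        truth = None
        if truth_path is not None and Path(truth_path).exists():
            with open(truth_path) as fh:
                truth = json.load(fh)
        return cls(data=data, truth=truth)


def generate_cohort(params: SimulationParams) -> CohortTable:
    """Draw a longitudinal ROI cohort from the hierarchical generative model.

    Per group g and ROI r: alpha[g,r] ~ N(mean_intercept[g], sd_intercept[g])
    and beta[g,r] ~ N(mean_age[g], sd_age[g]).  A subject of age a in group g
    has true annualized change alpha + beta * (a - center) / scale in every
    region; the follow-up measurement adds N(0, residual_sd) noise to the
    *annualized* change (i.e. noise scaled by the interval enters the
    follow-up value), so observed change = true change + residual noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lobe_map = params.resolved_lobe_map()
    rois = list(lobe_map.index)
    R = params.n_roi

    alpha = {}
    beta = {}
    for g in GROUPS:
        alpha[g] = rng.normal(params.hyper_mean_intercept[g], params.hyper_sd_intercept[g], R)
        beta[g] = rng.normal(params.hyper_mean_age[g], params.hyper_sd_age[g], R)

    n_by_group = {"LPA": params.n_lpa, "PCA": params.n_pca, "CU": params.n_control}
    rows = []
    truth = {
        "alpha": {g: dict(zip(rois, map(float, alpha[g]))) for g in GROUPS},
        "beta": {g: dict(zip(rois, map(float, beta[g]))) for g in GROUPS},
        "residual_sd": np.asarray(params.residual_sd, dtype=float).tolist(),
        "seed": params.seed,
    }

    sid = 0
    for g in GROUPS:
        for _ in range(n_by_group[g]):
            sid += 1
            subject = f"sub-{sid:04d}"
            age = rng.uniform(*params.age_range)
            interval = rng.uniform(*params.interval_range)
            years = interval / DAYS_PER_YEAR
            x = (age - params.age_center) / params.age_scale
            baseline = rng.normal(params.baseline_mean[g], params.baseline_sd, R)
            baseline = np.clip(baseline, 0.05, None)  # SUVR-like values stay positive
            true_change = alpha[g] + beta[g] * x
            # "per_region" accepts a length-R residual_sd vector; "shared" a scalar
            sd = np.broadcast_to(np.asarray(params.residual_sd, dtype=float), (R,))
            noise = rng.normal(0.0, 1.0, R) * sd
            followup = baseline + true_change * years + noise * years
            for tp, values in (("baseline", baseline), ("followup", followup)):
                for r_i, roi in enumerate(rois):
                    rows.append((subject, g, age, roi, lobe_map.iloc[r_i],
                                 params.modality, tp, values[r_i], interval))

    data = pd.DataFrame(rows, columns=list(CohortTable.REQUIRED_COLUMNS))
    return CohortTable(data=data, truth=truth)


@dataclass
class AtlasPhantom:
    """Small 3D phantom: uptake + integer atlas labels + GM probability.

    Label 0 is background; ROI labels are 1..n_roi and ``reference_label``
    marks the reference region.  ``roi_medians`` records the intended
    tissue-masked median per label (the construction target).
    """

    uptake: np.ndarray
    labels: np.ndarray
    gm_probability: np.ndarray
    roi_medians: dict
    reference_label: int

    def write(self, directory, prefix: str = "phantom") -> dict:
        """Write uptake/labels/gm as NIfTI volumes; returns the paths."""
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4)
        paths = {}
        for name, arr, dtype in (
            ("uptake", self.uptake, np.float64),
            ("labels", self.labels, np.int16),
            ("gm", self.gm_probability, np.float64),
        ):
            img = nib.Nifti1Image(arr.astype(dtype), affine)
            path = directory / f"{prefix}_{name}.nii"
            nib.save(img, str(path))
            paths[name] = path
        return paths


def _block_coords(shape, n_blocks, block=(3, 3, 1)):
    """Corner coordinates for n_blocks disjoint blocks tiling `shape`."""
    nx = shape[0] // block[0]
    ny = shape[1] // block[1]
    nz = shape[2] // block[2]
    if nx * ny * nz < n_blocks:
        raise ValueError(
            f"shape {shape} too small to host {n_blocks} blocks of size {block}"
        )
    coords = []
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                coords.append((ix * block[0], iy * block[1], iz * block[2]))
                if len(coords) == n_blocks:
                    return coords, block
    return coords, block


def _exact_median_values(rng, k: int, target: float, spread: float) -> np.ndarray:
    """k (odd) values whose sample median is exactly `target`."""
    v = rng.normal(0.0, spread, k)
    v = v - np.median(v)  # middle order statistic becomes exactly 0
    return v + target


def generate_phantom(
    n_roi: int,
    roi_medians,
    reference_median: float,
    shape=(18, 18, 3),
    seed: int = 0,
    followup_scales=None,
    mask_threshold: float = 0.5,
):
    """Build a (baseline, follow-up) phantom pair with exact ROI medians.

    Each ROI occupies a 3x3x1 block; 5 of its 9 voxels carry GM probability
    0.9 (inside the tissue mask) and are constructed so their median equals
    the target exactly, while the other 4 carry GM probability 0.2 and
    deliberately corrupted uptake, so the mask matters.  The follow-up
    phantom scales each ROI's masked voxels by ``followup_scales`` (default
    1.05 everywhere, i.e. 5% uptake increase).
    """
    roi_medians = np.asarray(roi_medians, dtype=float)
    if roi_medians.shape != (n_roi,):
        raise ValueError(f"roi_medians must have length {n_roi}")
    if followup_scales is None:
        followup_scales = np.full(n_roi, 1.05)
    followup_scales = np.asarray(followup_scales, dtype=float)
    if followup_scales.shape != (n_roi,):
        raise ValueError(f"followup_scales must have length {n_roi}")

    rng = np.random.default_rng(seed)
    reference_label = n_roi + 1
    coords, block = _block_coords(shape, n_roi + 1)

    labels = np.zeros(shape, dtype=np.int16)
    gm = np.zeros(shape, dtype=float)
    uptake_base = np.zeros(shape, dtype=float)
    uptake_follow = np.zeros(shape, dtype=float)

    targets = list(roi_medians) + [reference_median]
    scales = list(followup_scales) + [1.0]  # reference region is stable
    medians_base = {}
    medians_follow = {}
    for lab_idx, ((x, y, z), target, scale) in enumerate(zip(coords, targets, scales)):
        label = lab_idx + 1
        sl = (slice(x, x + block[0]), slice(y, y + block[1]), slice(z, z + block[2]))
        labels[sl] = label
        block_gm = np.full(block, 0.2)
        flat = block_gm.reshape(-1)
        flat[:5] = 0.9  # odd masked-voxel count -> median is an attained value
        gm[sl] = block_gm

        spread = 0.1 * max(abs(target), 1.0)
        masked_vals = _exact_median_values(rng, 5, target, spread)
        junk = target + rng.normal(0.0, 5.0 * spread, 4) + 10.0 * spread
        block_up = np.concatenate([masked_vals, junk]).reshape(block)
        uptake_base[sl] = block_up
        follow_vals = _exact_median_values(rng, 5, target * scale, spread)
        uptake_follow[sl] = np.concatenate([follow_vals, junk]).reshape(block)
        medians_base[label] = float(target)
        medians_follow[label] = float(target * scale)

    baseline = AtlasPhantom(uptake_base, labels, gm, medians_base, reference_label)
    followup = AtlasPhantom(uptake_follow, labels.copy(), gm.copy(), medians_follow,
                            reference_label)
    return baseline, followup
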