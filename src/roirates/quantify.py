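"""ROI quantification: SUVR, annualized changes, volume normalization.

Implements the standard longitudinal tau-PET / MRI quantities:

* median ROI uptake under a grey-matter tissue mask,
* SUVR = ROI median / reference-region (cerebellar crus) median,
* annualized SUVR change = (follow-up - baseline) / interval in years,
* annualized log-Jacobian = log-Jacobian / interval_days * 365.25
  (interpretable as annual percent grey-matter volume change),
* intracranial-volume normalization of ROI volumes,
* amyloid positivity from a global SUVR cut-point (1.42).

A year is 365.25 days throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
AMYLOID_CUTPOINT = 1.42
DEFAULT_MASK_THRESHOLD = 0.5


class EmptyRoiError(ValueError):
    """No voxels of an ROI survive the tissue mask."""


def extract_roi_median(uptake, labels, gm_probability, roi_id,
                       mask_threshold=DEFAULT_MASK_THRESHOLD):
    """Median uptake over voxels with ``labels == roi_id`` and GM prob > threshold."""
    uptake = np.asarray(uptake)
    labels = np.asarray(labels)
    gm_probability = np.asarray(gm_probability)
    if not (uptake.shape == labels.shape == gm_probability.shape):
        raise ValueError("uptake, labels and gm_probability must share one shape")
    mask = (labels == roi_id) & (gm_probability > mask_threshold)
    if not mask.any():
        raise EmptyRoiError(
            f"ROI {roi_id}: no voxels remain after masking at gm > {mask_threshold}"
        )
    return float(np.median(uptake[mask]))


def extract_all_roi_medians(uptake, labels, gm_probability,
                            mask_threshold=DEFAULT_MASK_THRESHOLD) -> pd.Series:
    """Tissue-masked median per non-background label present in ``labels``."""
    ids = np.unique(np.asarray(labels))
    ids = ids[ids != 0]
    medians = {
        int(i): extract_roi_median(uptake, labels, gm_probability, int(i), mask_threshold)
        for i in ids
    }
    return pd.Series(medians, name="median_uptake")


def compute_suvr(roi_medians, reference_median) -> pd.Series:
    """Standard uptake value ratios: ROI median / reference-region median."""
    if reference_median <= 0:
        raise ValueError(f"invalid reference region: median {reference_median} <= 0")
    medians = pd.Series(roi_medians, dtype=float)
    return (medians / float(reference_median)).rename("suvr")


def annualized_suvr_change(suvr_baseline, suvr_followup, interval_days):
    """(follow-up SUVR - baseline SUVR) / interval in years."""
    interval_days = np.asarray(interval_days, dtype=float)
    if np.any(interval_days <= 0):
        raise ValueError("interval_days must be positive")
    out = (np.asarray(suvr_followup, dtype=float)
           - np.asarray(suvr_baseline, dtype=float)) / (interval_days / DAYS_PER_YEAR)
    return out if out.ndim else float(out)


def annualize_log_jacobian(log_jacobian, interval_days):
    """Log-Jacobian divided by the scan interval in days, times 365.25."""
    interval_days = np.asarray(interval_days, dtype=float)
    if np.any(interval_days <= 0):
        raise ValueError("interval_days must be positive")
    out = np.asarray(log_jacobian, dtype=float) / interval_days * DAYS_PER_YEAR
    return out if out.ndim else float(out)


def normalize_roi_volume(roi_volume, total_intracranial_volume):
    """ROI volume as a fraction of total intracranial volume."""
    tiv = np.asarray(total_intracranial_volume, dtype=float)
    if np.any(tiv <= 0):
        raise ValueError("total intracranial volume must be positive")
    out = np.asarray(roi_volume, dtype=float) / tiv
    return out if out.ndim else float(out)


def classify_amyloid(global_suvr, cutpoint: float = AMYLOID_CUTPOINT) -> str:
    """Amyloid status from global SUVR; the cut-point itself is positive."""
    if global_suvr <= 0:
        raise ValueError("global SUVR must be positive")
    return "positive" if global_suvr >= cutpoint else "negative"


def suvr_table_from_volumes(uptake, labels, gm_probability, reference_label,
                            mask_threshold=DEFAULT_MASK_THRESHOLD) -> pd.Series:
    """Extract medians for every labelled ROI and normalize by the reference.

    Returns SUVR indexed by label id, the reference label included (its
    SUVR is identically 1.0 by construction).
    """
    medians = extract_all_roi_medians(uptake, labels, gm_probability, mask_threshold)
    if reference_label not in medians.index:
        raise EmptyRoiError(f"reference label {reference_label} absent from label volume")
    return compute_suvr(medians, medians.loc[reference_label])
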