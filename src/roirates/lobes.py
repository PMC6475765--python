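"""Lobe-wise posterior comparisons.

Regional posterior contrast draws are reduced to unweighted lobe averages
and compared pairwise: entry p[row, col] of the comparison matrix is the
posterior probability that the column lobe has a higher annualized change
than the row lobe, estimated as the fraction of retained draws in which the
column's lobe-average exceeds the row's.  Tied draws count 0.5 to each
side, which preserves the complement identity p[i, j] + p[j, i] = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import default_lobe_map

LOBES = (
    "frontal", "sensorimotor", "medial temporal", "lateral temporal",
    "medial parietal", "lateral parietal", "medial occipital", "lateral occipital",
)


def lobe_average(contrast_draws, rois, lobe_map=None, lobes=None):
    """Per-draw unweighted mean of member-region draws for each lobe.

    Returns ``(lobe_draws, lobe_order)`` where ``lobe_draws`` has the
    region axis replaced by a lobe axis.
    """
    if lobe_map is None:
        lobe_map = default_lobe_map()
    lobe_map = pd.Series(lobe_map)
    arr = np.asarray(contrast_draws, dtype=float)
    rois = list(rois)
    if arr.shape[-1] != len(rois):
        raise ValueError("last axis of draws must match the ROI list")
    missing = [r for r in rois if r not in lobe_map.index]
    if missing:
        raise ValueError(f"ROIs with no lobe assignment: {missing[:5]}")
    assignment = lobe_map.loc[rois]
    if lobes is None:
        lobes = tuple(l for l in LOBES if l in set(assignment)) or tuple(pd.unique(assignment))
    out = np.empty(arr.shape[:-1] + (len(lobes),))
    for li, lobe in enumerate(lobes):
        members = np.flatnonzero((assignment == lobe).to_numpy())
        if members.size == 0:
            raise ValueError(f"lobe {lobe!r} has no member ROIs")
        out[..., li] = arr[..., members].mean(axis=-1)
    return out, tuple(lobes)


@dataclass
class LobeComparisonMatrix:
    """Pairwise posterior probabilities that one lobe changes faster.

    ``p[i, j]`` is the probability that lobe ``j`` (column) has a higher
    annualized change than lobe ``i`` (row); the diagonal is NaN.
    """

    lobes: tuple
    p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=list(self.lobes), columns=list(self.lobes))

    def display(self) -> pd.DataFrame:
        """Table-style formatting with '<0.001' / '>0.999' clipping."""
        def fmt(v):
            if np.isnan(v):
                return ""
            if v < 0.001:
                return "<0.001"
            if v > 0.999:
                return ">0.999"
            return f"{v:.3f}"
        return self.to_frame().map(fmt)


def comparison_matrix(lobe_draws, lobes) -> LobeComparisonMatrix:
    """Fraction of draws in which each column lobe exceeds each row lobe."""
    arr = np.asarray(lobe_draws, dtype=float)
    arr = arr.reshape(-1, arr.shape[-1])
    n_draws, L = arr.shape
    if n_draws < 100:
        raise ValueError(f"need >= 100 draws, got {n_draws}")
    p = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            greater = np.count_nonzero(arr[:, j] > arr[:, i])
            ties = np.count_nonzero(arr[:, j] == arr[:, i])
            p[i, j] = (greater + 0.5 * ties) / n_draws
    return LobeComparisonMatrix(lobes=tuple(lobes), p=p)
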