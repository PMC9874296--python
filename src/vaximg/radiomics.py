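"""A small radiomics feature set plus correlation-threshold selection.

Only three features are implemented — first-order energy, first-order
interquartile range and the Gray Level Dependence Matrix (GLDM) Dependence
Non-Uniformity — the texture/intensity descriptors that proved informative
for immune-response prediction in this pipeline.  Definitions follow the
IBSI conventions: equal-width discretisation over the in-ROI intensity
range, 26-connected neighbourhoods, neighbours outside the ROI ignored.
"""
from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .volumes import ROIMask, ScalarVolume

log = logging.getLogger(__name__)


def first_order_energy(vol: ScalarVolume, roi: ROIMask) -> float:
    """Sum of squared intensities over the ROI."""
    roi.check_compatible(vol)
    roi.require_nonempty()
    vals = vol.data[roi.mask]
    return float(np.sum(vals ** 2))


def first_order_iqr(vol: ScalarVolume, roi: ROIMask) -> float:
    """Interquartile range (P75 − P25) of in-ROI intensities.

    Percentiles use linear interpolation between order statistics.
    """
    roi.check_compatible(vol)
    if roi.voxel_count < 4:
        raise ValueError("IQR requires at least 4 in-mask voxels")
    vals = vol.data[roi.mask]
    q75, q25 = np.percentile(vals, [75, 25], method="linear")
    return float(q75 - q25)


def discretize(vol: ScalarVolume, roi: ROIMask, n_bins: int) -> np.ndarray:
    """Equal-width gray-level discretisation over the in-ROI range.

    Returns an integer array (gray levels 1..n_bins inside the ROI, 0
    outside).  A constant ROI maps every voxel to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    roi.check_compatible(vol)
    roi.require_nonempty()
    vals = vol.data[roi.mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.data.shape, dtype=np.int64)
    if hi == lo:
        levels[roi.mask] = 1
        return levels
    width = (hi - lo) / n_bins
    binned = np.minimum((vals - lo) // width, n_bins - 1).astype(np.int64) + 1
    levels[roi.mask] = binned
    return levels


_OFFSETS_26 = [
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
]


def gldm_dnu(
    vol: ScalarVolume,
    roi: ROIMask,
    n_bins: int = 32,
    alpha: int = 0,
    connectivity: int = 26,
) -> float:
    """Gray Level Dependence Matrix — Dependence Non-Uniformity.

    For each ROI voxel the *dependence* is the number of 26-connected
    neighbours (inside the ROI) whose discretised gray level differs by at
    most ``alpha``.  With P(g, d) the count of voxels at gray level g and
    dependence d, DNU = Σ_d (Σ_g P(g, d))² / N.  Large values indicate a
    homogeneous dependence structure; heterogeneous textures score lower
    per voxel.
    """
    if connectivity != 26:
        raise ValueError("only 26-connectivity is supported")
    levels = discretize(vol, roi, n_bins)
    mask = roi.mask

    dependence = np.zeros(mask.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        shifted_levels = _shift(levels, off)
        shifted_mask = _shift(mask, off)
        ok = mask & shifted_mask & (np.abs(levels - shifted_levels) <= alpha)
        dependence += ok

    dep_in = dependence[mask]
    n = dep_in.size
    # Σ_g P(g, d) over g is just the dependence-count histogram.
    counts = np.bincount(dep_in)
    return float(np.sum(counts.astype(float) ** 2) / n)


def _shift(arr: np.ndarray, offset) -> np.ndarray:
    """Array shifted by an integer offset, zero-padded at the borders."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for ax, o in enumerate(offset):
        n = arr.shape[ax]
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def extract_features(
    vol: ScalarVolume, roi: ROIMask, n_bins: int = 32, alpha: int = 0
) -> dict:
    """All implemented features with their discretisation provenance."""
    return {
        "first_order_energy": first_order_energy(vol, roi),
        "first_order_iqr": first_order_iqr(vol, roi),
        "gldm_dnu": gldm_dnu(vol, roi, n_bins=n_bins, alpha=alpha),
        "n_bins": n_bins,
        "alpha": alpha,
        "roi_voxels": roi.voxel_count,
    }


def correlate_features(
    features: pd.DataFrame, outcome, threshold: float = 0.5
) -> pd.DataFrame:
    """Univariate feature selection by Pearson correlation threshold.

    Correlates every feature column with the outcome, drops constant
    features (undefined r, logged), and returns features with |r| ≥
    threshold sorted by |r| descending, with their two-sided p-values.
    """
    outcome = np.asarray(outcome, dtype=float)
    if len(features) != len(outcome):
        raise ValueError(
            f"features has {len(features)} rows but outcome has {len(outcome)}"
        )
    if len(outcome) < 3:
        raise ValueError("correlation selection needs at least 3 samples")
    if np.ptp(outcome) == 0:
        raise ValueError("outcome is constant; correlation undefined")

    rows = []
    for name in features.columns:
        x = np.asarray(features[name], dtype=float)
        if np.ptp(x) == 0:
            log.info("dropping constant feature %r (correlation undefined)", name)
            continue
        r, p = sps.pearsonr(x, outcome)
        rows.append({"feature": name, "r": float(r), "abs_r": abs(float(r)),
                     "p_value": float(p)})
    ranked = pd.DataFrame(rows, columns=["feature", "r", "abs_r", "p_value"])
    ranked = ranked[ranked["abs_r"] >= threshold]
    return ranked.sort_values("abs_r", ascending=False).reset_index(drop=True)
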