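"""MR relaxometry and enhancement volumetry.

T2/M0 parameter maps are fitted voxel-wise from a multi-echo acquisition
under the mono-exponential decay model ``S(TE) = M0 * exp(-TE / T2)``.
Enhancement volumetry thresholds a scalar image at the contralateral
control-region mean + k·SD and sums the supra-threshold voxel volume.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .volumes import MultiEchoVolume, ROIMask, ScalarVolume

#: Flag value for voxels where the relaxation fit is undefined.
INVALID = np.nan


class EmptyFitError(ValueError):
    """No voxel in the volume admits a valid relaxation fit."""


def _monoexp(te, m0, t2):
    return m0 * np.exp(-te / t2)


def fit_t2_map(
    vol: MultiEchoVolume,
    method: str = "log_linear",
    min_signal: float = 0.0,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Fit per-voxel T2 (ms) and M0 (a.u.) parameter maps.

    ``log_linear`` performs unweighted ordinary least squares of ln S
    against TE (closed form, vectorised); ``nonlinear`` refines each valid
    voxel by Levenberg–Marquardt least squares on the exponential itself,
    initialised from the log-linear solution.

    A voxel is fitted only when every echo is strictly positive and at or
    above ``min_signal``; other voxels — and voxels whose decay slope is
    non-negative (non-decaying signal, infinite apparent T2) — carry NaN in
    the T2 map.  M0 is still reported wherever the intercept is defined.
    """
    if method not in ("log_linear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    if vol.n_echoes < 2:
        raise ValueError("at least two echoes are required")

    te = vol.echo_times
    shape = vol.data.shape[1:]
    signals = vol.data.reshape(vol.n_echoes, -1)

    floor = max(min_signal, 0.0)
    valid = np.all(signals > 0, axis=0) & np.all(signals >= floor, axis=0)
    if not valid.any():
        raise EmptyFitError("no voxel has all echoes above the signal floor")

    t2 = np.full(signals.shape[1], INVALID)
    m0 = np.full(signals.shape[1], INVALID)

    logs = np.log(signals[:, valid])
    te_c = te - te.mean()
    slope = te_c @ (logs - logs.mean(axis=0)) / (te_c @ te_c)
    intercept = logs.mean(axis=0) - slope * te.mean()

    decaying = slope < -1e-12
    t2_valid = np.full(slope.shape, INVALID)
    t2_valid[decaying] = -1.0 / slope[decaying]
    m0_valid = np.exp(intercept)

    if method == "nonlinear":
        sig_valid = signals[:, valid]
        for i in range(sig_valid.shape[1]):
            y = sig_valid[:, i]
            if not np.isfinite(t2_valid[i]):
                continue  # keep degenerate voxels flagged
            p0 = (m0_valid[i], t2_valid[i])
            try:
                popt, _ = curve_fit(_monoexp, te, y, p0=p0, maxfev=2000)
            except RuntimeError:
                continue  # keep log-linear estimate on non-convergence
            if popt[1] > 0:
                m0_valid[i], t2_valid[i] = popt

    t2[valid] = t2_valid
    m0[valid] = m0_valid
    return (
        ScalarVolume(t2.reshape(shape), vol.spacing, unit="ms"),
        ScalarVolume(m0.reshape(shape), vol.spacing, unit="a.u."),
    )


def enhancement_mask(
    post_vol: ScalarVolume,
    control_roi: ROIMask,
    search_roi: ROIMask,
    k_sd: float = 2.0,
) -> tuple[ROIMask, float]:
    """Threshold-based signal-enhancement volumetry.

    The threshold is mean + ``k_sd``·SD of the voxels in the contralateral
    control region (population SD, ddof=0).  Voxels of ``search_roi``
    strictly above the threshold form the enhancement mask; ties at exactly
    the threshold are excluded.  Returns the mask and its volume in mm³.
    """
    control_roi.check_compatible(post_vol)
    search_roi.check_compatible(post_vol)
    control_roi.require_nonempty()
    if np.any(control_roi.mask & search_roi.mask):
        raise ValueError("control and search ROIs must be disjoint")

    control_vals = post_vol.data[control_roi.mask]
    threshold = float(control_vals.mean() + k_sd * control_vals.std(ddof=0))
    mask = search_roi.mask & (post_vol.data > threshold)
    out = ROIMask(mask, post_vol.spacing, label=f"enhancement>{threshold:g}")
    return out, out.volume_mm3


def roi_stats(vol: ScalarVolume, roi: ROIMask) -> dict:
    """Mean, SD (population), volume and voxel count over an ROI."""
    roi.check_compatible(vol)
    roi.require_nonempty()
    vals = vol.data[roi.mask]
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=0)),
        "volume_mm3": roi.volume_mm3,
        "voxel_count": roi.voxel_count,
    }
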