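"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (explicit loops, O(n²) scans) so
they stay independent of the vectorised / spatial-index implementations
they check.
"""
from __future__ import annotations

import numpy as np
import pytest

from vaximg.volumes import ROIMask, ScalarVolume


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_proximity_mean(a_xy: np.ndarray, b_xy: np.ndarray, radius: float,
                         same: bool) -> float:
    """O(n²) mean count of B cells within radius (inclusive) of each A."""
    counts = []
    for i, p in enumerate(a_xy):
        c = 0
        for j, q in enumerate(b_xy):
            if same and i == j:
                continue
            if np.hypot(p[0] - q[0], p[1] - q[1]) <= radius:
                c += 1
        counts.append(c)
    return float(np.mean(counts))


def brute_nn_median(a_xy: np.ndarray, b_xy: np.ndarray, same: bool) -> float:
    """O(n²) median nearest-neighbour distance from A cells to B cells."""
    nearest = []
    for i, p in enumerate(a_xy):
        best = np.inf
        for j, q in enumerate(b_xy):
            if same and i == j:
                continue
            d = np.hypot(p[0] - q[0], p[1] - q[1])
            best = min(best, d)
        nearest.append(best)
    return float(np.median(nearest))


def brute_gldm_dnu(data: np.ndarray, mask: np.ndarray, n_bins: int,
                   alpha: int = 0) -> float:
    """Naive-loop GLDM dependence non-uniformity."""
    vals = data[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(data.shape, dtype=int)
    if hi == lo:
        levels[mask] = 1
    else:
        width = (hi - lo) / n_bins
        for idx in np.argwhere(mask):
            g = int((data[tuple(idx)] - lo) // width)
            levels[tuple(idx)] = min(g, n_bins - 1) + 1
    deps = []
    nz, ny, nx = data.shape
    for z, y, x in np.argwhere(mask):
        d = 0
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dz, dy, dx) == (0, 0, 0):
                        continue
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                        continue
                    if mask[zz, yy, xx] and abs(int(levels[zz, yy, xx]) - int(levels[z, y, x])) <= alpha:
                        d += 1
        deps.append(d)
    n = len(deps)
    dnu = 0.0
    for d in set(deps):
        dnu += deps.count(d) ** 2
    return dnu / n


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """Random 8×8×8 scalar volume with anisotropic spacing."""
    data = rng.normal(100.0, 15.0, (8, 8, 8))
    return ScalarVolume(data, spacing=(1.5, 0.469, 0.469))


@pytest.fixture
def full_roi(small_volume):
    return ROIMask(np.ones(small_volume.data.shape, dtype=bool),
                   small_volume.spacing, label="all")
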