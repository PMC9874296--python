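"""Spatial relationship metrics between phenotyped cell populations.

Two metrics characterise how cell type A relates to cell type B within a
sample's mosaic (2-D section coordinates in µm):

* proximity count — the average number of B cells within a radius
  (default 15 µm, boundary inclusive) of each A cell;
* nearest-neighbour distance — the median, over A cells, of the distance
  to the closest B cell.

Distances are centroid-to-centroid.  Cells from different ROIs of the same
sample interact through the global mosaic coordinates; distances are never
computed across samples.  Edge effects at section borders are not
corrected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class SpatialMetricResult:
    sample_id: str
    type_a: str
    type_b: str
    metric: str              # "proximity_count" | "nn_distance"
    value: float             # mean count, or median distance in µm
    n_a: int
    n_b: int
    defined: bool = True


def _coords(table: pd.DataFrame, phenotype: str) -> np.ndarray:
    sel = table["phenotype"] == phenotype
    return table.loc[sel, ["x_um", "y_um"]].to_numpy(dtype=float)


def _per_sample(table: pd.DataFrame):
    if "phenotype" not in table.columns:
        raise ValueError("cell table has no 'phenotype' column; run phenotyping first")
    for sample_id, sub in table.groupby("sample_id", sort=True):
        yield str(sample_id), sub


def proximity_count(
    table: pd.DataFrame, type_a: str, type_b: str, radius_um: float = 15.0
) -> list[SpatialMetricResult]:
    """Average number of B cells within ``radius_um`` of each A cell.

    The boundary is inclusive (a B cell at exactly the radius counts).
    When A and B are the same phenotype the cell itself is excluded.
    Samples missing either phenotype yield a flagged undefined result
    rather than a silent zero.
    """
    if radius_um < 0:
        raise ValueError("radius_um must be non-negative")
    results = []
    for sample_id, sub in _per_sample(table):
        a = _coords(sub, type_a)
        b = _coords(sub, type_b)
        if len(a) == 0 or len(b) == 0:
            results.append(SpatialMetricResult(
                sample_id, type_a, type_b, "proximity_count",
                np.nan, len(a), len(b), defined=False))
            continue
        tree = cKDTree(b)
        counts = np.array([
            len(tree.query_ball_point(p, radius_um)) for p in a
        ], dtype=float)
        if type_a == type_b:
            counts -= 1.0  # remove self-match
        results.append(SpatialMetricResult(
            sample_id, type_a, type_b, "proximity_count",
            float(counts.mean()), len(a), len(b)))
    return results


def nearest_neighbor_distance(
    table: pd.DataFrame, type_a: str, type_b: str
) -> list[SpatialMetricResult]:
    """Median distance from each A cell to its nearest B cell (µm).

    Self-pairs are excluded when A == B (which then requires at least two
    A cells in the sample).  The median uses linear interpolation for even
    counts.
    """
    results = []
    for sample_id, sub in _per_sample(table):
        a = _coords(sub, type_a)
        b = _coords(sub, type_b)
        same = type_a == type_b
        if len(a) == 0 or len(b) == 0 or (same and len(a) < 2):
            results.append(SpatialMetricResult(
                sample_id, type_a, type_b, "nn_distance",
                np.nan, len(a), len(b), defined=False))
            continue
        tree = cKDTree(b)
        if same:
            dists, _ = tree.query(a, k=2)
            nearest = dists[:, 1]
        else:
            nearest, _ = tree.query(a, k=1)
        results.append(SpatialMetricResult(
            sample_id, type_a, type_b, "nn_distance",
            float(np.median(nearest)), len(a), len(b)))
    return results


def results_frame(results: list[SpatialMetricResult]) -> pd.DataFrame:
    """Long-format table of spatial metric results."""
    return pd.DataFrame([vars(r) for r in results])
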