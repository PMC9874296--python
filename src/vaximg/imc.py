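"""Single-cell phenotyping from imaging-mass-cytometry intensity tables.

The pipeline mirrors standard suspension/imaging cytometry practice on a
per-cell table (one row per segmented cell, per-channel mean pixel
intensity as a protein-expression surrogate):

1. z-normalise each channel (population SD);
2. gate each channel with a two-component univariate Gaussian mixture —
   the higher-mean component is "positive", cells are called positive when
   their posterior for that component exceeds 0.5 (the Bayes rule for the
   fitted mixture);
3. cluster cells by K-means on the z-scored channels;
4. assign each cluster a phenotype from rule-based canonical-marker
   definitions (e.g. follicular dendritic cells are CD21+CD20−), applied
   in an explicit priority order so the assignment is deterministic;
5. compute per-sample cell-type ratios.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)


@dataclass
class PhenotypeDefinition:
    """Canonical-marker rule for one phenotype.

    A cluster matches when all ``required_positive`` channels are
    cluster-positive and all ``required_negative`` channels are
    cluster-negative.  ``priority`` orders competing rules (lower wins);
    when omitted, list position is used.
    """

    name: str
    required_positive: tuple[str, ...]
    required_negative: tuple[str, ...] = ()
    priority: int | None = None

    def __post_init__(self) -> None:
        self.required_positive = tuple(self.required_positive)
        self.required_negative = tuple(self.required_negative)
        if not self.required_positive:
            raise ValueError(f"phenotype {self.name!r} needs at least one positive marker")
        overlap = set(self.required_positive) & set(self.required_negative)
        if overlap:
            raise ValueError(
                f"phenotype {self.name!r} lists {sorted(overlap)} as both "
                "positive and negative"
            )


#: The lymph-node phenotype rules used throughout this pipeline, in
#: priority order (most specific first, so e.g. follicular B cells are not
#: swallowed by the generic CD20+ B-cell rule).
def default_phenotype_definitions() -> list[PhenotypeDefinition]:
    return [
        PhenotypeDefinition("follicular dendritic cell", ("CD21",), ("CD20",)),
        PhenotypeDefinition("follicular B cell", ("CD20", "Bcl6")),
        PhenotypeDefinition("follicular helper T cell", ("CD3", "Bcl6")),
        PhenotypeDefinition("regulatory T cell", ("CD4", "FoxP3")),
        PhenotypeDefinition("CD8 T cell", ("CD3", "CD8")),
        PhenotypeDefinition("helper T cell", ("CD3", "CD4")),
        PhenotypeDefinition("phagocyte", ("CD68",)),
        PhenotypeDefinition("B cell", ("CD20",)),
        PhenotypeDefinition("antigen presenting cell", ("MHCII",)),
    ]


UNASSIGNED = "unassigned"


def _channel_columns(table: pd.DataFrame, channels) -> list[str]:
    missing = [c for c in channels if c not in table.columns]
    if missing:
        raise ValueError(f"cell table is missing channel columns {missing}")
    return list(channels)


def znormalize(
    table: pd.DataFrame, channels, scope: str = "per_sample"
) -> pd.DataFrame:
    """Add per-channel z-score columns ``z_<channel>``.

    ``scope`` controls the normalisation population: ``"per_sample"``
    (default) standardises within each sample, ``"pooled"`` across the
    whole table.  SD is the population SD (ddof=0).  Raw intensities are
    retained.
    """
    if scope not in ("per_sample", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")
    channels = _channel_columns(table, channels)
    out = table.copy()
    groups = [("", out)] if scope == "pooled" else list(out.groupby("sample_id"))
    for ch in channels:
        z = np.empty(len(out), dtype=float)
        for key, sub in groups:
            vals = sub[ch].to_numpy(dtype=float)
            sd = vals.std(ddof=0)
            if sd == 0:
                where = f" in sample {key!r}" if scope == "per_sample" else ""
                raise ValueError(f"channel {ch!r} has zero variance{where}")
            z[out.index.get_indexer(sub.index)] = (vals - vals.mean()) / sd
        out[f"z_{ch}"] = z
    return out


@dataclass
class GateResult:
    """Outcome of a two-component Gaussian-mixture gate on one channel."""

    positive: np.ndarray
    means: tuple[float, float]       # (negative, positive) component means
    sds: tuple[float, float]
    weights: tuple[float, float]
    converged: bool
    degenerate: bool = False         # components nearly coincide

    @property
    def positive_fraction(self) -> float:
        return float(self.positive.mean())


def gate_channel(
    z_values, seed: int = 0, n_init: int = 5, min_cells: int = 20
) -> GateResult:
    """Gate one channel's z-scores with a 2-component Gaussian mixture.

    The component with the larger mean is the expressing ("positive")
    population; a cell is called positive when its posterior probability of
    that component exceeds 0.5.  Near-coincident components (mean
    separation < 0.1 pooled SD) are flagged degenerate but still gated.
    """
    z = np.asarray(z_values, dtype=float).reshape(-1, 1)
    if z.shape[0] < min_cells:
        raise ValueError(f"gating needs at least {min_cells} cells, got {z.shape[0]}")
    if np.ptp(z) == 0:
        raise ValueError("all values identical; mixture gate is degenerate")

    gm = GaussianMixture(
        n_components=2, n_init=n_init, random_state=seed, max_iter=500
    ).fit(z)
    if not gm.converged_:
        raise RuntimeError(
            "EM did not converge after 500 iterations "
            f"(lower bound {gm.lower_bound_:.4g}); inspect the channel distribution"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    pos_comp = int(np.argmax(means))
    neg_comp = 1 - pos_comp

    pooled_sd = float(z.std(ddof=0))
    degenerate = abs(means[pos_comp] - means[neg_comp]) < 0.1 * pooled_sd
    if degenerate:
        log.warning(
            "near-degenerate mixture (component separation %.3g < 0.1 pooled sd)",
            abs(means[pos_comp] - means[neg_comp]),
        )

    posterior = gm.predict_proba(z)[:, pos_comp]
    return GateResult(
        positive=posterior > 0.5,
        means=(float(means[neg_comp]), float(means[pos_comp])),
        sds=(float(sds[neg_comp]), float(sds[pos_comp])),
        weights=(float(weights[neg_comp]), float(weights[pos_comp])),
        converged=bool(gm.converged_),
        degenerate=degenerate,
    )


def gate_table(
    table: pd.DataFrame, channels, seed: int = 0, n_init: int = 5,
    min_cells: int = 20,
) -> tuple[pd.DataFrame, dict[str, GateResult]]:
    """Gate every channel; adds boolean ``pos_<channel>`` columns."""
    channels = _channel_columns(table, channels)
    out = table.copy()
    gates: dict[str, GateResult] = {}
    for i, ch in enumerate(channels):
        zcol = f"z_{ch}"
        if zcol not in out.columns:
            raise ValueError(f"missing {zcol!r}; run znormalize first")
        res = gate_channel(
            out[zcol].to_numpy(), seed=seed + i, n_init=n_init, min_cells=min_cells
        )
        out[f"pos_{ch}"] = res.positive
        gates[ch] = res
    return out, gates


def cluster_cells(
    table: pd.DataFrame, channels, k: int = 15, seed: int = 0, n_init: int = 10
) -> pd.DataFrame:
    """K-means on the z-scored channels; adds a ``cluster_id`` column.

    k-means++ initialisation with ``n_init`` restarts, best inertia kept;
    deterministic under a fixed seed.
    """
    channels = _channel_columns(table, channels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the number of cells ({len(table)})")
    zcols = [f"z_{c}" for c in channels]
    missing = [c for c in zcols if c not in table.columns]
    if missing:
        raise ValueError(f"missing z-score columns {missing}; run znormalize first")
    X = table[zcols].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    out = table.copy()
    out["cluster_id"] = km.labels_
    return out


def assign_phenotypes(
    table: pd.DataFrame,
    definitions: list[PhenotypeDefinition] | None = None,
    channels=None,
    majority_frac: float = 0.5,
) -> pd.DataFrame:
    """Label each cluster with the first matching phenotype rule.

    A channel counts as cluster-positive when more than ``majority_frac``
    of the cluster's cells are gated positive for it.  Rules are evaluated
    in priority order; clusters matching no rule become ``"unassigned"``.
    Two rules sharing the same explicit priority that both match a cluster
    raise an error demanding an explicit ordering.
    """
    if definitions is None:
        definitions = default_phenotype_definitions()
    if "cluster_id" not in table.columns:
        raise ValueError("missing 'cluster_id'; run cluster_cells first")
    defs = [
        (d.priority if d.priority is not None else i, i, d)
        for i, d in enumerate(definitions)
    ]
    defs.sort(key=lambda t: (t[0], t[1]))

    if channels is None:
        channels = [c[4:] for c in table.columns if c.startswith("pos_")]
    for d in definitions:
        needed = set(d.required_positive) | set(d.required_negative)
        missing = needed - set(channels)
        if missing:
            raise ValueError(f"phenotype {d.name!r} references ungated channels {sorted(missing)}")

    out = table.copy()
    out["phenotype"] = UNASSIGNED
    for cluster, sub in out.groupby("cluster_id"):
        cluster_pos = {
            ch: sub[f"pos_{ch}"].mean() > majority_frac for ch in channels
        }
        matched: list[tuple[int, PhenotypeDefinition]] = []
        for prio, _, d in defs:
            ok = all(cluster_pos[ch] for ch in d.required_positive) and not any(
                cluster_pos[ch] for ch in d.required_negative
            )
            if ok:
                matched.append((prio, d))
        if not matched:
            continue
        best_prio = matched[0][0]
        at_best = [d for p, d in matched if p == best_prio]
        if len(at_best) > 1:
            names = [d.name for d in at_best]
            raise ValueError(
                f"cluster {cluster} matches {names} at equal priority {best_prio}; "
                "set explicit priorities on the definitions"
            )
        out.loc[sub.index, "phenotype"] = at_best[0].name
    return out


def cell_type_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample phenotype composition, aggregating all ROIs of a sample.

    Returns a tidy frame (sample_id, phenotype, count, ratio); ratios per
    sample sum to 1 and include the unassigned fraction.
    """
    if "phenotype" not in table.columns:
        raise ValueError("missing 'phenotype'; run assign_phenotypes first")
    rows = []
    for sample_id, sub in table.groupby("sample_id", sort=True):
        if len(sub) == 0:
            raise ValueError(f"sample {sample_id!r} has no cells")
        counts = sub["phenotype"].value_counts()
        for phenotype, count in counts.items():
            rows.append({
                "sample_id": sample_id, "phenotype": phenotype,
                "count": int(count), "ratio": float(count / len(sub)),
            })
    return pd.DataFrame(rows)


def run_imc_pipeline(
    table: pd.DataFrame,
    channels,
    definitions: list[PhenotypeDefinition] | None = None,
    scope: str = "per_sample",
    k: int = 15,
    seed: int = 0,
    n_init: int = 10,
    majority_frac: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, GateResult]]:
    """z-normalise → gate → cluster → phenotype → ratios, in one call."""
    normed = znormalize(table, channels, scope=scope)
    gated, gates = gate_table(normed, channels, seed=seed)
    clustered = cluster_cells(gated, channels, k=k, seed=seed, n_init=n_init)
    labelled = assign_phenotypes(
        clustered, definitions, channels=channels, majority_frac=majority_frac
    )
    ratios = cell_type_ratio(labelled)
    return labelled, ratios, gates
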