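"""ΔCt normalization, gene exclusions and rank-based hierarchical clustering.

ΔCt is computed cell-wise against the mean Ct of the housekeeping assays
(Ubc and Polr2a in the default panel); lower ΔCt = more transcript.
Cell-to-cell dissimilarity is 1 − Spearman rho of ΔCt profiles with Ward
linkage, the standard recipe for small targeted panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_core import CtMatrix, logger


@dataclass
class DeltaCtMatrix:
    """Housekeeping-normalized expression (cells x retained assays)."""

    values: pd.DataFrame
    cell_meta: pd.DataFrame
    assay_meta: pd.DataFrame
    excluded_assays: list[tuple[str, str]] = field(default_factory=list)  # (name, reason)
    dropped_cells: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def populations(self) -> pd.Series:
        return self.cell_meta["population_label"]


def delta_ct_normalize(
    ct: CtMatrix,
    housekeepers: list[str] | None = None,
) -> DeltaCtMatrix:
    """ΔCt[i, g] = Ct[i, g] − mean(Ct[i, housekeepers]).

    Cells in which any normalization housekeeper went undetected are dropped
    (and reported); housekeeper columns are removed from the result since
    they are normalization-only.  Undetected assay entries map to
    ``lod_ct − mean(housekeeper Ct)``, i.e. least expressed.
    """
    hks = housekeepers if housekeepers is not None else ct.housekeepers
    missing = [h for h in hks if h not in ct.values.columns]
    if missing:
        raise ValueError(f"housekeeper(s) not in panel: {missing}")

    hk_detected = ct.detected[hks].all(axis=1)
    dropped = list(ct.values.index[~hk_detected])
    if dropped:
        logger.warning("dropping %d cells with undetected housekeepers", len(dropped))
    if hk_detected.sum() == 0:
        raise ValueError("no cells with all housekeepers detected")

    vals = ct.values.loc[hk_detected]
    hk_mean = vals[hks].mean(axis=1)
    all_hk = [g for g in ct.values.columns if ct.assay_meta.loc[g, "is_housekeeper"]]
    retained = [g for g in ct.values.columns if g not in all_hk]
    delta = vals[retained].sub(hk_mean, axis=0)

    return DeltaCtMatrix(
        values=delta,
        cell_meta=ct.cell_meta.loc[hk_detected].copy(),
        assay_meta=ct.assay_meta.loc[retained].copy(),
        excluded_assays=[(g, "housekeeper") for g in all_hk],
        dropped_cells=dropped,
    )


def apply_gene_exclusions(dct: DeltaCtMatrix, drop: list[str]) -> DeltaCtMatrix:
    """Remove the named assays; names not present raise a warning only.

    With the default 48-assay panel, dropping the 3 housekeepers (already
    removed at normalization) plus Cdkn2a and Egfl7 leaves 43 analysis genes.
    """
    present = [g for g in drop if g in dct.values.columns]
    absent = [g for g in drop if g not in dct.values.columns]
    if absent:
        warnings.warn(f"exclusion list names absent assays (skipped): {absent}")
    retained = [g for g in dct.values.columns if g not in set(present)]
    return DeltaCtMatrix(
        values=dct.values[retained].copy(),
        cell_meta=dct.cell_meta.copy(),
        assay_meta=dct.assay_meta.loc[retained].copy(),
        excluded_assays=dct.excluded_assays + [(g, "excluded") for g in present],
        dropped_cells=list(dct.dropped_cells),
    )


def spearman_distance_matrix(values: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 − Spearman rho between cell profiles (rows).

    A constant profile has undefined rank correlation; its distances are set
    to 1 (uninformative) with a warning, and its self-distance to 0.
    """
    arr = values.to_numpy(dtype=float)
    constant = np.array([np.unique(row).size == 1 for row in arr])
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant cell profile(s); distances set to 1")
    # Spearman rho = Pearson correlation of mid-ranked profiles; computed
    # directly so constant profiles degrade to NaN rows instead of
    # collapsing the whole matrix
    ranks = pd.DataFrame(arr).rank(axis=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    dist = 1.0 - rho
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return dist


def _to_newick(tree: hierarchy.ClusterNode, labels: list[str]) -> str:
    if tree.is_leaf():
        return labels[tree.id]
    left = _to_newick(tree.get_left(), labels)
    right = _to_newick(tree.get_right(), labels)
    dl = tree.dist - tree.get_left().dist
    dr = tree.dist - tree.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


@dataclass
class ClusterResult:
    labels: pd.Series  # cluster id per cell, 1-based
    linkage: np.ndarray
    newick: str


def hierarchical_cluster(dct: DeltaCtMatrix, n_cell_clusters: int = 2) -> ClusterResult:
    """Ward clustering of cells on Spearman distances, cut at a cluster count."""
    if dct.values.shape[0] < 2 or dct.values.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 genes to cluster")
    dist = spearman_distance_matrix(dct.values)
    z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    labels = hierarchy.fcluster(z, t=n_cell_clusters, criterion="maxclust")
    newick = _to_newick(hierarchy.to_tree(z), list(dct.values.index)) + ";"
    return ClusterResult(
        labels=pd.Series(labels, index=dct.values.index, name="cluster"),
        linkage=z,
        newick=newick,
    )
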