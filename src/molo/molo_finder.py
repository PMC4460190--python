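"""The core search: locate the molecularly overlapping (MolO) subpopulation.

A functionally homogeneous stem-cell subpopulation should appear in the 2D
map as a neighborhood that (i) mixes all sorting strategies and (ii) mixes
them in proportion to each strategy's published repopulation probability.
For every cell we therefore compare its k-nearest-neighbor strategy
composition with the normalized repopulation weights using the
Jensen-Shannon divergence (symmetric, bounded by ln 2 nats, defined for
zero entries), and calibrate the call against a permutation null: a cell is
MolO when its divergence falls at or below the alpha-quantile of the
divergences obtained under random strategy-label permutations.  Cells from
non-weighted (non-HSC) strategies are never assigned MolO/NoMO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import Embedding2D
from .io_core import IndexSortTable, logger
from .qpcr_panel import DeltaCtMatrix
from .stats_utils import benjamini_hochberg, rank_sum_test


@dataclass
class WeightVector:
    """Per-strategy repopulation probabilities and their normalized weights."""

    probabilities: pd.Series  # strategy -> p in [0, 1]

    def __post_init__(self) -> None:
        p = self.probabilities
        if ((p < 0) | (p > 1)).any():
            raise ValueError("repopulation probabilities must lie in [0, 1]")
        if p.sum() <= 0:
            raise ValueError("at least one strategy needs a positive probability")

    @property
    def weights(self) -> pd.Series:
        return self.probabilities / self.probabilities.sum()

    @property
    def strategies(self) -> list[str]:
        return list(self.probabilities.index)


@dataclass
class MolOAssignment:
    """Per-cell MolO/NoMO/non-HSC labels with divergence scores."""

    table: pd.DataFrame  # index cell_id: label, divergence, p_perm, strategy
    k: int
    alpha: float
    weights: WeightVector

    @property
    def molo_cells(self) -> pd.Index:
        return self.table.index[self.table["label"] == "MolO"]

    @property
    def nomo_cells(self) -> pd.Index:
        return self.table.index[self.table["label"] == "NoMO"]


def _neighbor_indices(xy: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest cells to each cell, itself included.

    Distance ties are broken by cell index order (lower index first), which
    makes the neighborhoods — and everything downstream — order-stable.
    """
    n = xy.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available cells")
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
    return order[:, :k]


def _jsd_to_weights(comp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Jensen-Shannon divergence (nats) of each composition row against w."""
    m = 0.5 * (comp + w)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_c = np.where(comp > 0, comp * (np.log(comp) - np.log(m)), 0.0).sum(-1)
        kl_w = np.where(w > 0, w * (np.log(w) - np.log(m)), 0.0).sum(-1)
    return 0.5 * kl_c + 0.5 * kl_w


def jensen_shannon(p, q) -> float:
    """JSD between two probability vectors, in nats (0 .. ln 2)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(_jsd_to_weights(p[None, :], q[None, :])[0])


def neighborhood_composition(
    emb: Embedding2D,
    labels: pd.Series,
    k: int,
) -> pd.DataFrame:
    """Per-cell strategy composition of the k-nearest neighborhood (self
    included); rows sum to one."""
    labels = labels.loc[emb.coords.index]
    strategies = sorted(labels.unique(), key=str)
    codes = pd.Categorical(labels, categories=strategies).codes
    neigh = _neighbor_indices(emb.xy, k)
    neigh_codes = codes[neigh]
    comp = np.stack([(neigh_codes == s).sum(1) for s in range(len(strategies))], axis=1) / k
    return pd.DataFrame(comp, index=emb.coords.index, columns=strategies)


def identify_molo(
    emb: Embedding2D,
    labels: pd.Series,
    weights: WeightVector,
    k: int = 20,
    alpha: float = 0.95,
    n_perm: int = 1000,
    seed: int = 0,
) -> MolOAssignment:
    """Label each weighted-strategy cell MolO or NoMO.

    The per-cell divergence d_i = JSD(composition_i, weights) is ranked
    (mid-rank, so the discrete tie structure of k-multinomial compositions
    introduces no bias) within a null of divergences computed from ``n_perm``
    random permutations of the strategy labels; d_i at or below the
    alpha-quantile of its null makes the cell MolO.  Cells of strategies
    without a weight are labeled non-HSC and ignored by the null.
    """
    if (weights.probabilities > 0).sum() < 2:
        raise ValueError("need >= 2 strategies with nonzero weight")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable divergence threshold")

    labels = labels.loc[emb.coords.index]
    strategies = weights.strategies
    is_hsc = labels.isin(strategies).to_numpy()
    hsc_idx = emb.coords.index[is_hsc]
    xy = emb.xy[is_hsc]
    codes = pd.Categorical(labels[is_hsc], categories=strategies).codes.astype(np.int64)
    n = len(hsc_idx)
    if k >= n:
        raise ValueError(f"k={k} must be below the {n} weighted-strategy cells")

    w = weights.weights.reindex(strategies).to_numpy()
    neigh = _neighbor_indices(xy, k)
    s_count = len(strategies)

    def compositions(code_vec: np.ndarray) -> np.ndarray:
        nc = code_vec[neigh]
        return np.stack([(nc == s).sum(1) for s in range(s_count)], axis=1) / k

    d_obs = _jsd_to_weights(compositions(codes), w)

    rng = np.random.default_rng(seed)
    null = np.empty((n, n_perm))
    for b in range(n_perm):
        null[:, b] = _jsd_to_weights(compositions(rng.permutation(codes)), w)

    less = (null < d_obs[:, None] - 1e-12).sum(1)
    equal = (np.abs(null - d_obs[:, None]) <= 1e-12).sum(1)
    p_perm = (less + 0.5 * (equal + 1.0)) / (n_perm + 1.0)
    is_molo = p_perm <= alpha

    table = pd.DataFrame(
        {
            "label": "non-HSC",
            "divergence": np.nan,
            "p_perm": np.nan,
            "strategy": labels,
        },
        index=emb.coords.index,
    )
    table.loc[hsc_idx, "divergence"] = d_obs
    table.loc[hsc_idx, "p_perm"] = p_perm
    table.loc[hsc_idx, "label"] = np.where(is_molo, "MolO", "NoMO")
    logger.info("identify_molo: %d MolO / %d NoMO of %d weighted cells", int(is_molo.sum()), int((~is_molo).sum()), n)
    return MolOAssignment(table, k=k, alpha=alpha, weights=weights)


def molo_differential_genes(
    dct: DeltaCtMatrix,
    assign: MolOAssignment,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene, MolO vs NoMO, BH-corrected.

    Direction is reported on the expression scale: "up_in_molo" means lower
    ΔCt (more transcript) in MolO cells.
    """
    molo = dct.values.loc[dct.values.index.intersection(assign.molo_cells)]
    nomo = dct.values.loc[dct.values.index.intersection(assign.nomo_cells)]
    if len(molo) < 5 or len(nomo) < 5:
        raise ValueError(f"need >= 5 cells per group, got MolO={len(molo)}, NoMO={len(nomo)}")
    rows = []
    for g in dct.genes:
        a, b = molo[g].to_numpy(), nomo[g].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = rank_sum_test(a, b)
        med_diff = float(np.median(a) - np.median(b))
        rows.append({
            "gene": g,
            "median_delta_ct_diff": med_diff,
            "direction": "up_in_molo" if med_diff < 0 else "down_in_molo",
            "p": p,
        })
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] <= fdr
    return out.sort_values("q")


@dataclass
class MarkerEnrichment:
    table: pd.DataFrame  # index channel: median_diff, direction, p, q
    excluded_cells: list[str]


def index_marker_enrichment(
    idx: IndexSortTable,
    assign: MolOAssignment,
    fdr: float = 0.05,
) -> MarkerEnrichment:
    """Rank surface channels by MolO vs NoMO Wilcoxon q-value.

    The output is a ranked shortlist for gate design; cells without index
    rows are listed and excluded.
    """
    molo = [c for c in assign.molo_cells if c in idx.channels.index]
    nomo = [c for c in assign.nomo_cells if c in idx.channels.index]
    excluded = [c for c in list(assign.molo_cells) + list(assign.nomo_cells) if c not in idx.channels.index]
    if excluded:
        logger.warning("index_marker_enrichment: %d cells lack index rows", len(excluded))
    if not molo or not nomo:
        raise ValueError("both MolO and NoMO groups need joinable index rows")
    rows = []
    for ch in idx.channel_names:
        a, b = idx.channels.loc[molo, ch].to_numpy(), idx.channels.loc[nomo, ch].to_numpy()
        p = rank_sum_test(a, b)
        diff = float(np.median(a) - np.median(b))
        rows.append({"channel": ch, "median_diff": diff,
                     "direction": "up_in_molo" if diff > 0 else "down_in_molo", "p": p})
    table = pd.DataFrame(rows).set_index("channel")
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    return MarkerEnrichment(table.sort_values("q"), excluded)
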