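"""Linking surface phenotype to single-cell function.

Sequenced and transplanted cells share the same index-sort channels, so a
joint 2D map of their (jointly z-scored) marker intensities places cells
with molecular information next to cells with functional information.  The
SuMO score is the signed projection of each cell onto the first
total-least-squares axis of that map, oriented so that it correlates
non-negatively with the MolO score of the sequenced cells.  The module
also calls transplant outcomes (>= 1% donor WBC chimerism at week 16
and/or 24; alpha/beta/gamma/delta lineage-bias subtypes), estimates
functional-cell frequency by single-hit Poisson limiting dilution, and
generalizes the clustering/enrichment recipe to the mammary colony assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import brentq
from scipy.stats import chi2, fisher_exact

from .embedding import Embedding2D, embed_tsne
from .io_core import IndexSortTable, TransplantRecord, logger
from .molo_classifier import MolOScore
from .stats_utils import benjamini_hochberg, rank_sum_test, spearman_test

LINEAGES = ("WBC", "GM", "B", "T")


# ---------------------------------------------------------------------------
# Joint embedding and the SuMO axis
# ---------------------------------------------------------------------------


def joint_marker_embedding(
    idx_seq: IndexSortTable,
    idx_tx: IndexSortTable,
    perplexity: float = 30.0,
    seed: int = 0,
    init_dims: int = 30,
) -> Embedding2D:
    """Embed sequenced + transplanted cells on jointly z-scored channels.

    Both tables must expose the same channel set (matched by name); the
    result's coords carry a ``source`` column ("seq"/"tx").
    """
    a, b = set(idx_seq.channel_names), set(idx_tx.channel_names)
    if a != b:
        raise ValueError(f"channel mismatch between tables: only-seq={sorted(a - b)}, only-tx={sorted(b - a)}")
    channels = sorted(a)
    pooled = pd.concat([idx_seq.channels[channels], idx_tx.channels[channels]])
    if pooled.index.duplicated().any():
        raise ValueError("sequenced and transplanted cells must have distinct cell_ids")
    z = (pooled - pooled.mean()) / pooled.std(ddof=0).replace(0.0, 1.0)
    emb = embed_tsne(z, perplexity=perplexity, seed=seed, init_dims=init_dims, input_kind="surface_markers")
    emb.coords["source"] = ["seq"] * len(idx_seq.channels) + ["tx"] * len(idx_tx.channels)
    return emb


@dataclass
class SuMOScore:
    """Projection of each cell onto the fitted axis of the marker map."""

    scores: pd.Series
    axis: np.ndarray  # unit 2-vector
    oriented: bool  # True when the sign was fixed against MolO scores


def fit_sumo_axis(emb: Embedding2D, molo: MolOScore | pd.Series | None = None) -> SuMOScore:
    """First total-least-squares direction of the 2D cloud; score = projection.

    The axis is the leading eigenvector of the coordinate covariance
    (symmetric in the two arbitrary map axes).  When MolO scores are given
    for >= 3 embedded cells, the sign is chosen so that
    Spearman(SuMO, MolO) >= 0 on those cells.
    """
    xy = emb.xy
    if xy.shape[0] < 3:
        raise ValueError("need >= 3 embedded points to fit an axis")
    centered = xy - xy.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    if evals[-1] > 0 and evals[0] > 0 and evals[-1] / evals[0] < 1.05:
        warnings.warn("marker cloud is nearly isotropic; SuMO axis is weakly determined")
    scores = pd.Series(centered @ axis, index=emb.coords.index, name="sumo_score")

    oriented = False
    molo_scores = molo.scores if isinstance(molo, MolOScore) else molo
    if molo_scores is not None:
        common = scores.index.intersection(molo_scores.index)
        if len(common) >= 3:
            rho, _ = spearman_test(scores.loc[common].to_numpy(), molo_scores.loc[common].to_numpy())
            if np.isfinite(rho) and rho < 0:
                axis = -axis
                scores = -scores
            oriented = True
    return SuMOScore(scores=scores, axis=axis, oriented=oriented)


def ward_partition(emb: Embedding2D, k: int = 2) -> pd.Series:
    """Ward clustering of embedding coordinates into k regions."""
    z = hierarchy.linkage(emb.xy, method="ward")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=emb.coords.index, name="region")


def region_enrichment(
    emb: Embedding2D,
    partition: pd.Series,
    values: pd.DataFrame,
) -> pd.DataFrame:
    """Test per-cell values across the two map regions.

    Scalar columns get a two-sided Wilcoxon rank-sum; boolean/binary columns
    a Fisher exact test.  BH correction runs across the tested columns.
    Cells absent from a column (NaN) are ignored for that column.
    """
    regions = sorted(partition.unique())
    if len(regions) != 2:
        raise ValueError(f"partition must have exactly 2 regions, got {len(regions)}")
    rows = []
    for col in values.columns:
        v = values[col].dropna()
        g1 = v[partition.loc[v.index] == regions[0]]
        g2 = v[partition.loc[v.index] == regions[1]]
        if g1.empty or g2.empty:
            raise ValueError(f"empty region for value {col!r}")
        uniq = set(v.unique())
        if v.dtype == bool or uniq <= {0, 1, True, False}:
            tab = np.array(
                [[(g1 > 0).sum(), (g1 <= 0).sum()], [(g2 > 0).sum(), (g2 <= 0).sum()]],
                dtype=int,
            )
            p = float(fisher_exact(tab)[1])
            effect = float((g1 > 0).mean() - (g2 > 0).mean())
            kind = "fisher"
        else:
            p = rank_sum_test(g1.to_numpy(), g2.to_numpy())
            effect = float(np.median(g1) - np.median(g2))
            kind = "wilcoxon"
        rows.append({"value": col, "test": kind, "effect": effect, "p": p,
                     "enriched_region": regions[0] if effect > 0 else regions[1]})
    out = pd.DataFrame(rows).set_index("value")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Transplant outcome calling
# ---------------------------------------------------------------------------


@dataclass
class RepopulationCall:
    mouse_id: str
    donor_wbc_pct: dict[float, float]  # week -> donor WBC %
    repopulated: bool
    subtype: str  # alpha | beta | gamma | delta | none
    gm_lymphoid_ratio: float | None = None


def call_repopulation(
    records: list[TransplantRecord],
    threshold_pct: float = 1.0,
    subtype_high: float = 2.0,
    subtype_low: float = 0.25,
    weeks: tuple[float, float] = (16.0, 24.0),
) -> list[RepopulationCall]:
    """Call repopulation and lineage-bias subtype per mouse.

    A mouse is repopulated when donor WBC chimerism reaches the threshold
    (inclusive) at week 16 and/or 24.  The subtype follows the ratio of the
    donor GM contribution to the mean donor B/T contribution at week 16:
    alpha above ``subtype_high``, beta between the cutoffs, gamma below
    ``subtype_low`` (with WBC at threshold), and delta for mice repopulated
    in some lineage but with sub-threshold balanced output.  Mice missing a
    subtype lineage are flagged "none".
    """
    calls = []
    for rec in records:
        wbc = {}
        for wk in weeks:
            pct = rec.donor_pct(wk, "WBC")
            if pct is not None:
                wbc[wk] = pct
        if not wbc:
            raise ValueError(f"{rec.mouse_id}: no WBC measurement at weeks {weeks}")
        repop = any(p >= threshold_pct for p in wbc.values())

        gm = rec.donor_pct(weeks[0], "GM")
        bb = rec.donor_pct(weeks[0], "B")
        tt = rec.donor_pct(weeks[0], "T")
        ratio = None
        subtype = "none"
        if gm is None or bb is None or tt is None:
            logger.warning("%s: missing lineage for subtype call", rec.mouse_id)
        elif repop:
            lymph = (bb + tt) / 2.0
            ratio = np.inf if lymph == 0 else gm / lymph
            wk0_wbc = wbc.get(weeks[0], 0.0)
            if ratio > subtype_high:
                subtype = "alpha"
            elif ratio >= subtype_low:
                subtype = "beta"
            elif wk0_wbc >= threshold_pct:
                subtype = "gamma"
            else:
                any_lineage = any(
                    (rec.donor_pct(weeks[0], li) or 0.0) >= threshold_pct for li in LINEAGES
                )
                subtype = "delta" if any_lineage else "none"
        calls.append(
            RepopulationCall(
                mouse_id=rec.mouse_id,
                donor_wbc_pct=wbc,
                repopulated=repop,
                subtype=subtype,
                gm_lymphoid_ratio=None if ratio is None else float(ratio),
            )
        )
    return calls


def calls_to_frame(calls: list[RepopulationCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"mouse_id": c.mouse_id, "repopulated": c.repopulated, "subtype": c.subtype,
               "gm_lymphoid_ratio": c.gm_lymphoid_ratio}
        for wk, pct in c.donor_wbc_pct.items():
            row[f"donor_wbc_pct_wk{int(wk)}"] = pct
        rows.append(row)
    return pd.DataFrame(rows).set_index("mouse_id")


# ---------------------------------------------------------------------------
# Limiting dilution
# ---------------------------------------------------------------------------


@dataclass
class LDAResult:
    """Single-hit Poisson frequency estimate with a likelihood-ratio CI."""

    frequency: float  # per cell, in [0, 1]
    ci_low: float
    ci_high: float
    unbounded: bool  # True when every mouse was positive (estimate at bound)
    table: pd.DataFrame  # dose, n_mice, n_negative

    @property
    def one_in(self) -> float:
        return np.inf if self.frequency == 0 else 1.0 / self.frequency


def _lda_loglik(f: float, dose: np.ndarray, neg: np.ndarray, pos: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        log_p_neg = -f * dose
        log_p_pos = np.log1p(-np.exp(-f * dose))
    return float((neg * log_p_neg + pos * log_p_pos).sum())


def limiting_dilution(
    doses: list[int],
    n_mice: list[int],
    n_negative: list[int],
) -> LDAResult:
    """Maximum-likelihood stem-cell frequency from dose/negative counts.

    Under the single-hit model P(negative | dose d) = exp(−f·d).  The 95%
    CI inverts the likelihood ratio at the chi-square(1) 0.95 quantile.
    All-negative designs give f̂ = 0; all-positive designs report the lower
    CI bound with the point estimate pinned to 1 and flagged unbounded.
    """
    dose = np.asarray(doses, dtype=float)
    mice = np.asarray(n_mice, dtype=int)
    neg = np.asarray(n_negative, dtype=int)
    if not (dose.size == mice.size == neg.size):
        raise ValueError("doses, n_mice and n_negative must have equal length")
    if ((neg < 0) | (neg > mice)).any():
        raise ValueError("need 0 <= n_negative <= n_mice for every dose")
    pos = mice - neg
    if ((dose == 0) & (pos > 0)).any():
        raise ValueError("a positive mouse at dose 0 violates the single-hit model")
    keep = dose > 0
    dose, neg, pos = dose[keep], neg[keep], pos[keep]
    table = pd.DataFrame({"dose": dose.astype(int), "n_mice": (neg + pos), "n_negative": neg})

    crit = chi2.ppf(0.95, df=1) / 2.0

    if pos.sum() == 0:
        # boundary MLE at 0; upper CI from the LR bound
        ll0 = 0.0
        hi = brentq(lambda f: _lda_loglik(f, dose, neg, pos) - (ll0 - crit), 1e-12, 1.0)
        return LDAResult(0.0, 0.0, float(hi), False, table)

    def score(f: float) -> float:
        e = np.exp(-f * dose)
        return float((-neg * dose + pos * dose * e / (1.0 - e)).sum())

    if neg.sum() == 0 or score(1.0) > 0:
        f_hat = 1.0
        unbounded = True
    else:
        f_hat = brentq(score, 1e-12, 1.0)
        unbounded = False

    ll_max = _lda_loglik(f_hat, dose, neg, pos)

    def lr_gap(f: float) -> float:
        return _lda_loglik(f, dose, neg, pos) - (ll_max - crit)

    lo = brentq(lr_gap, 1e-12, f_hat) if lr_gap(1e-12) < 0 else 0.0
    hi = 1.0 if unbounded or lr_gap(1.0) > 0 else brentq(lr_gap, f_hat, 1.0)
    return LDAResult(float(f_hat), float(lo), float(hi), unbounded, table)


# ---------------------------------------------------------------------------
# Mammary generalization
# ---------------------------------------------------------------------------


@dataclass
class MammaryResult:
    clusters: pd.Series  # per well
    best_cluster: int
    cfe_fold: pd.DataFrame  # per patient: cfe_overall, cfe_cluster, fold
    marker_tests: pd.DataFrame
    embedding: Embedding2D


def mammary_pipeline(
    colony_table: pd.DataFrame,
    k_clusters: int = 2,
    perplexity: float = 30.0,
    seed: int = 0,
) -> MammaryResult:
    """Per-patient z-score, pooled t-SNE, Ward cut, CFE fold, marker tests.

    ``colony_table`` needs a ``patient_id`` column, a binary ``colony``
    column and numeric channel columns; each patient needs >= 20 wells.
    The cluster with maximal pooled colony-forming efficiency is reported,
    with per-patient fold = CFE(cluster ∩ patient) / CFE(patient); a patient
    without colonies gets an undefined (NaN) fold and a warning.
    """
    if "patient_id" not in colony_table.columns or "colony" not in colony_table.columns:
        raise ValueError("colony table needs patient_id and colony columns")
    sizes = colony_table.groupby("patient_id").size()
    small = sizes[sizes < 20]
    if not small.empty:
        raise ValueError(f"patients with < 20 wells: {small.to_dict()}")
    channels = [c for c in colony_table.columns if c not in ("patient_id", "colony")]
    z = colony_table[channels].copy().astype(float)
    for _, idx in colony_table.groupby("patient_id").groups.items():
        block = z.loc[idx]
        z.loc[idx] = (block - block.mean()) / block.std(ddof=0).replace(0.0, 1.0)

    emb = embed_tsne(z, perplexity=perplexity, seed=seed, input_kind="surface_markers")
    clusters = ward_partition(emb, k=k_clusters)

    colony = colony_table["colony"].astype(int)
    cfe_by_cluster = colony.groupby(clusters).mean()
    best = int(cfe_by_cluster.idxmax())

    rows = []
    for patient, idx in colony_table.groupby("patient_id").groups.items():
        overall = colony.loc[idx].mean()
        in_cluster = idx[clusters.loc[idx] == best]
        cfe_cluster = colony.loc[in_cluster].mean() if len(in_cluster) else np.nan
        if overall == 0:
            warnings.warn(f"{patient}: no colonies; fold undefined")
            fold = np.nan
        else:
            fold = cfe_cluster / overall
        rows.append({"patient_id": patient, "cfe_overall": overall,
                     "cfe_cluster": cfe_cluster, "fold": fold})
    cfe = pd.DataFrame(rows).set_index("patient_id")

    in_best = clusters == best
    tests = []
    for ch in channels:
        a = z.loc[in_best, ch].to_numpy()
        b = z.loc[~in_best, ch].to_numpy()
        p = rank_sum_test(a, b)
        diff = float(np.median(a) - np.median(b))
        tests.append({"channel": ch, "median_diff": diff,
                      "direction": "up_in_cluster" if diff > 0 else "down_in_cluster", "p": p})
    marker_tests = pd.DataFrame(tests).set_index("channel")
    marker_tests["q"] = benjamini_hochberg(marker_tests["p"].to_numpy())
    marker_tests = marker_tests.sort_values("q")

    return MammaryResult(
        clusters=clusters,
        best_cluster=best,
        cfe_fold=cfe,
        marker_tests=marker_tests,
        embedding=emb,
    )
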