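"""Synthetic single-cell fixtures with a planted MolO subpopulation.

The generator emulates the five input kinds the pipeline consumes:

* a multi-strategy single-cell qPCR panel in which a latent "MolO" state —
  shared across sorting strategies — carries a common Ct profile while
  non-MolO cells follow strategy-specific profiles,
* a genes x cells scRNA-seq count matrix (negative binomial biology,
  Poisson ERCC spike-ins, per-cell size factors, a planted MolO signature),
* index-sort channel intensities with MolO-linked marker shifts
  (CD150 and Sca-1 up, CD48 down, EPCR up),
* per-mouse transplant outcome tables whose repopulation probability is a
  logistic function of the latent MolO state, and
* a per-patient mammary colony table with a planted EpCAM-high / SSC-low
  colony-forming cluster.

Each strategy contributes ``cells_per_strategy`` cells and a cell is MolO
with its strategy's repopulation probability, so the MolO pool mixes the
strategies in proportion to those probabilities — exactly the compositional
structure the neighborhood-weighting search assumes.  All randomness flows
from ``SimSpec.seed`` through named sub-streams, so identical specs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import CountsMatrix, CtMatrix, IndexSortTable, TransplantRecord

HOUSEKEEPERS = ("Ubc", "Polr2a", "Actb")
EXCLUDED_GENES = ("Cdkn2a", "Egfl7")

#: the 43 analysis genes of the synthetic qPCR panel
PANEL_GENES = (
    "Bptf", "Cbfa2t3", "Cdkn1c", "Clu", "Ctla2a", "Dnmt3a", "Egr1", "Erg",
    "Ets2", "Etv6", "Fli1", "Gata1", "Gata2", "Gata3", "Gfi1", "Gfi1b",
    "Hhex", "Hoxa9", "Hoxb4", "Ifitm1", "Itga2b", "Ldb1", "Lmo2", "Ly6a",
    "Lyl1", "Meis1", "Mpl", "Muc13", "Myb", "Mycn", "Ndn", "Nfe2",
    "Notch1", "Pbx1", "Procr", "Ptpn14", "Rbpj", "Runx1", "Slamf1", "Spi1",
    "Tal1", "Tcf7", "vWF",
)

#: panel genes carrying the planted MolO ΔCt shift
DEFAULT_SIGNATURE_GENES = (
    "Procr", "vWF", "Itga2b", "Slamf1", "Ly6a", "Cdkn1c", "Ets2", "Gata1",
    "Mpl", "Ifitm1", "Ptpn14", "Gfi1b", "Clu", "Muc13", "Ctla2a",
)

#: RNA-seq-only genes that also carry the planted MolO fold change
EXTRA_SIGNATURE_GENES = ("Acap1", "Ctnna1", "Rgs1", "Glipr1", "Sult1a1")

INDEX_CHANNELS = (
    "FSC", "SSC", "7AAD", "Sca-1", "Lin", "CD34", "EPCR", "FLT3", "CD48",
    "CD150", "c-Kit",
)
_CHANNEL_BASE = {
    "FSC": 5.0, "SSC": 4.5, "7AAD": 1.0, "Sca-1": 3.0, "Lin": 1.5,
    "CD34": 1.2, "EPCR": 2.5, "FLT3": 1.2, "CD48": 1.5, "CD150": 2.8,
    "c-Kit": 3.5,
}

MAMMARY_CHANNELS = ("FSC", "SSC", "EpCAM", "CD49f", "ALDH", "CD24", "MUC1", "CD133")
_MAMMARY_BASE = {
    "FSC": 5.0, "SSC": 4.5, "EpCAM": 3.0, "CD49f": 2.5, "ALDH": 2.0,
    "CD24": 2.8, "MUC1": 2.2, "CD133": 1.8,
}


def _default_marker_effect() -> dict[str, float]:
    return {"CD150": 1.0, "Sca-1": 1.0, "CD48": -1.0, "EPCR": 1.0}


def _default_colony_effect() -> dict[str, float]:
    return {"EpCAM": 1.2, "SSC": -1.2}


@dataclass
class SimSpec:
    """Generative settings; the defaults define the study conditions.

    ``repop_prob`` holds per-strategy probabilities of durable self-renewal,
    the mixture-weight source for the MolO search.  The uniform 0.5 default
    is a placeholder, not a published value — set it from real repopulation
    data when emulating a specific sort design.
    """

    n_strategies: int = 5
    cells_per_strategy: int = 210
    repop_prob: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5, 0.5)
    n_genes: int = 48  # qPCR assays, housekeepers included
    molo_shift: Mapping[str, float] | None = None  # gene -> ΔCt shift for MolO cells
    dropout_midpoint: float = 28.0  # Ct at which detection probability is 1/2
    dropout_slope: float = 1.5
    ct_sd: float = 1.0
    strategy_effect: float = 2.5  # Ct offset magnitude of strategy-private profiles
    n_strategy_genes: int = 12  # genes per strategy-private profile
    nb_dispersion: float = 0.5  # NB dispersion of planted variable genes
    n_background_genes: int = 100  # Poisson "flat" genes in the count matrix
    rnaseq_fold_change: float = 4.0  # MolO/non-MolO mean ratio of signature genes
    spikein_means: tuple[float, ...] = tuple(np.geomspace(0.5, 2000.0, 50))
    size_factor_sigma: float = 0.3  # lognormal sd of per-cell size factors
    spikein_noise_cv2: float = 0.0  # extra multiplicative CV^2 on spike-in rates
    marker_effect: Mapping[str, float] = field(default_factory=_default_marker_effect)
    outcome_logit: tuple[float, float] = (-2.0, 4.0)  # intercept, MolO coefficient
    colony_effect: Mapping[str, float] = field(default_factory=_default_colony_effect)
    colony_prob: tuple[float, float] = (0.08, 0.45)  # non-progenitor, progenitor
    progenitor_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strategies < 1 or self.cells_per_strategy < 1:
            raise ValueError("need at least one strategy and one cell per strategy")
        if len(self.repop_prob) != self.n_strategies:
            raise ValueError("repop_prob length must equal n_strategies")
        if any(not (0.0 <= p <= 1.0) for p in self.repop_prob):
            raise ValueError("repopulation probabilities must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.n_genes < len(HOUSEKEEPERS) + len(EXCLUDED_GENES) + 1:
            raise ValueError("n_genes too small for housekeepers + excluded assays")

    # -- derived panel layout ------------------------------------------------

    @property
    def strategies(self) -> list[str]:
        return [f"HSC{i + 1}" for i in range(self.n_strategies)]

    @property
    def assay_names(self) -> list[str]:
        names = list(HOUSEKEEPERS) + list(EXCLUDED_GENES)
        pool = list(PANEL_GENES) + [f"G{i:03d}" for i in range(1, 1000)]
        names += pool[: self.n_genes - len(names)]
        return names

    @property
    def analysis_genes(self) -> list[str]:
        drop = set(HOUSEKEEPERS) | set(EXCLUDED_GENES)
        return [g for g in self.assay_names if g not in drop]

    def molo_shift_vector(self) -> dict[str, float]:
        if self.molo_shift is not None:
            return dict(self.molo_shift)
        present = [g for g in DEFAULT_SIGNATURE_GENES if g in self.assay_names]
        return {g: -3.0 for g in present}

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


def _detect_prob(mean_ct: np.ndarray, spec: SimSpec) -> np.ndarray:
    """Logistic detection probability: well-expressed (low Ct) genes detect."""
    return 1.0 / (1.0 + np.exp((mean_ct - spec.dropout_midpoint) / spec.dropout_slope))


def simulate_qpcr(spec: SimSpec) -> tuple[CtMatrix, pd.Series]:
    """Simulate the multi-strategy qPCR panel; returns (CtMatrix, MolO truth).

    MolO cells of every strategy share one Gaussian Ct profile (the base
    profile plus ``molo_shift``); non-MolO cells follow strategy-private
    profiles.  Detection follows a logistic function of the state-specific
    true mean; undetected entries are set to the limit of detection (40).
    """
    rng = spec._rng(11)
    assays = spec.assay_names
    n_assays = len(assays)
    lod = 40.0

    base = np.empty(n_assays)
    for i, g in enumerate(assays):
        if g in HOUSEKEEPERS:
            base[i] = rng.normal(15.0, 0.5)
        elif g == "Cdkn2a":
            base[i] = lod + 5.0  # never expressed in any cell type
        elif g == "Egfl7":
            base[i] = 26.0  # high-dropout assay
        else:
            base[i] = rng.uniform(18.0, 25.0)

    shift = spec.molo_shift_vector()
    molo_mean = base.copy()
    for g, s in shift.items():
        molo_mean[assays.index(g)] += s

    analysis_idx = [i for i, g in enumerate(assays) if g in spec.analysis_genes]
    strat_means = {}
    for s, strat in enumerate(spec.strategies):
        m = base.copy()
        picked = rng.choice(analysis_idx, size=min(spec.n_strategy_genes, len(analysis_idx)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=picked.size)
        m[picked] += signs * spec.strategy_effect
        strat_means[strat] = m

    cells, labels, wells, molo_flags = [], [], [], []
    rows_val, rows_det = [], []
    cell_rng = spec._rng(12)
    for strat in spec.strategies:
        p = spec.repop_prob[spec.strategies.index(strat)]
        for i in range(spec.cells_per_strategy):
            is_molo = bool(cell_rng.random() < p)
            mean = molo_mean if is_molo else strat_means[strat]
            tau = cell_rng.normal(0.0, 0.5)  # per-cell loading shift, removed by ΔCt
            ct = cell_rng.normal(mean + tau, spec.ct_sd)
            det = cell_rng.random(n_assays) < _detect_prob(mean, spec)
            ct = np.where(det, np.minimum(ct, lod - 1e-6), lod)
            cells.append(f"{strat}_c{i:04d}")
            labels.append(strat)
            wells.append(f"{strat}_w{i:04d}")
            molo_flags.append(is_molo)
            rows_val.append(ct)
            rows_det.append(det)

    index = pd.Index(cells, name="cell_id")
    values = pd.DataFrame(np.asarray(rows_val), index=index, columns=assays)
    detected = pd.DataFrame(np.asarray(rows_det), index=index, columns=assays)
    cell_meta = pd.DataFrame({"population_label": labels, "well_id": wells}, index=index)
    assay_meta = pd.DataFrame(
        {"is_housekeeper": [g in HOUSEKEEPERS for g in assays]},
        index=pd.Index(assays, name="gene_name"),
    )
    truth = pd.Series(molo_flags, index=index, name="molo")
    return CtMatrix(values, detected, cell_meta, assay_meta, lod_ct=lod), truth


def rnaseq_gene_table(spec: SimSpec) -> pd.DataFrame:
    """Per-gene generative parameters of the count matrix (deterministic in seed)."""
    rng = spec._rng(21)
    genes = list(spec.analysis_genes) + list(EXTRA_SIGNATURE_GENES)
    genes += [f"BG{i:03d}" for i in range(1, spec.n_background_genes + 1)]
    signature = set(spec.molo_shift_vector()) | set(EXTRA_SIGNATURE_GENES)
    rows = []
    for g in genes:
        mean = 10.0 ** rng.uniform(1.0, 2.5)  # 10 .. ~300 normalized counts
        sig = g in signature
        rows.append(
            {
                "gene_id": g,
                "base_mean": mean,
                "is_signature": sig,
                "dispersion": spec.nb_dispersion if sig else 0.0,
                "molo_fold": spec.rnaseq_fold_change if sig else 1.0,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_counts(spec: SimSpec, truth: pd.Series) -> CountsMatrix:
    """Simulate a genes x cells count matrix for the cells in ``truth``.

    Biological genes are negative binomial with a per-cell size factor;
    planted signature genes additionally have MolO-dependent means and the
    spec's NB dispersion (background genes are Poisson).  Spike-ins are
    Poisson at ``spikein_means`` times the size factor, optionally with
    extra multiplicative noise of squared CV ``spikein_noise_cv2``.
    """
    rng = spec._rng(22)
    cells = truth.index
    n_cells = len(cells)
    table = rnaseq_gene_table(spec)
    molo = truth.to_numpy().astype(float)

    size = np.exp(rng.normal(0.0, spec.size_factor_sigma, n_cells)) if spec.size_factor_sigma > 0 else np.ones(n_cells)

    blocks = []
    for g, row in table.iterrows():
        mean = row["base_mean"] * np.where(molo > 0, row["molo_fold"], 1.0) * size
        disp = row["dispersion"]
        if disp > 0:
            shape = 1.0 / disp
            lam = rng.gamma(shape, mean / shape)
            blocks.append(rng.poisson(lam))
        else:
            blocks.append(rng.poisson(mean))

    spike_names = [f"ERCC-{i + 1:05d}" for i in range(len(spec.spikein_means))]
    for m in spec.spikein_means:
        rate = m * size
        if spec.spikein_noise_cv2 > 0:
            shape = 1.0 / spec.spikein_noise_cv2
            rate = rate * rng.gamma(shape, 1.0 / shape, n_cells)
        blocks.append(rng.poisson(rate))

    gene_ids = list(table.index) + spike_names
    counts = pd.DataFrame(
        np.asarray(blocks, dtype=np.int64),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=cells,
    )
    gene_meta = pd.DataFrame(
        {"is_spikein": [g in set(spike_names) for g in gene_ids]},
        index=counts.index,
    )
    cell_meta = pd.DataFrame({"qc_pass": True}, index=pd.Index(cells, name="cell_id"))
    return CountsMatrix(counts, gene_meta, cell_meta)


def simulate_index(
    spec: SimSpec,
    truth: pd.Series,
    batch: str = "sort1",
    outcome: pd.Series | None = None,
) -> IndexSortTable:
    """Index-sort channel intensities: lognormal base + marker_effect x MolO."""
    rng = spec._rng(31)
    molo = truth.to_numpy().astype(float)
    data = {}
    for ch in INDEX_CHANNELS:
        effect = float(spec.marker_effect.get(ch, 0.0))
        data[ch] = rng.normal(_CHANNEL_BASE[ch], 0.5, len(truth)) + effect * molo
    chan = pd.DataFrame(data, index=truth.index)
    batch_id = pd.Series(batch, index=truth.index, name="batch_id")
    return IndexSortTable(chan, batch_id, outcome)


def simulate_transplants(
    spec: SimSpec,
    truth: pd.Series,
    dose: int = 1,
) -> tuple[list[TransplantRecord], pd.Series]:
    """One mouse per cell in ``truth``; repopulation ~ Bernoulli(logistic).

    Repopulated mice receive donor lineage counts yielding >= 1% chimerism
    in white blood cells at week 16; non-repopulated mice stay below 1%.
    """
    rng = spec._rng(32)
    b0, b1 = spec.outcome_logit
    records, flags = [], []
    lineages = ("WBC", "GM", "B", "T")
    for cell_id, is_molo in truth.items():
        p = 1.0 / (1.0 + np.exp(-(b0 + b1 * float(is_molo))))
        repop = bool(rng.random() < p)
        flags.append(repop)
        rows = []
        if repop:
            level = rng.uniform(5.0, 50.0)  # donor WBC % at week 16
            factors = np.exp(rng.normal(0.0, 0.3, len(lineages) - 1))
        for week, scale in ((8, 0.5), (16, 1.0), (24, 1.0)):
            for li, lineage in enumerate(lineages):
                recipient = rng.normal(10000.0, 500.0)
                if repop:
                    pct = level * scale if lineage == "WBC" else min(95.0, level * scale * factors[li - 1])
                    pct = max(pct, 1.0 if (lineage == "WBC" and week >= 16) else 0.05)
                else:
                    pct = rng.uniform(0.0, 0.5)
                donor = pct / (100.0 - pct) * recipient
                rows.append({"week": week, "lineage": lineage, "donor": donor, "recipient": recipient})
        records.append(TransplantRecord(f"mouse_{cell_id}", dose, pd.DataFrame(rows)))
    return records, pd.Series(flags, index=truth.index, name="repopulated")


def simulate_colonies(
    spec: SimSpec,
    n_patients: int = 5,
    wells_per_patient: int = 192,
) -> pd.DataFrame:
    """Mammary colony table: per-patient batches, planted progenitor cluster."""
    rng = spec._rng(41)
    rows = []
    for p in range(n_patients):
        patient = f"patient{p + 1}"
        offsets = {ch: rng.normal(0.0, 0.5) for ch in MAMMARY_CHANNELS}
        for w in range(wells_per_patient):
            prog = rng.random() < spec.progenitor_frac
            row = {"well_id": f"{patient}_w{w:03d}", "patient_id": patient}
            for ch in MAMMARY_CHANNELS:
                eff = float(spec.colony_effect.get(ch, 0.0))
                row[ch] = _MAMMARY_BASE[ch] + offsets[ch] + eff * prog + rng.normal(0.0, 0.5)
            row["colony"] = int(rng.random() < spec.colony_prob[1 if prog else 0])
            rows.append(row)
    return pd.DataFrame(rows).set_index("well_id")


def simulate_index_and_function(
    spec: SimSpec,
    truth: pd.Series,
) -> tuple[IndexSortTable, list[TransplantRecord], pd.DataFrame]:
    """Index table + transplant outcomes for the cells in ``truth``, plus a
    mammary colony table for the default patient design."""
    records, repop = simulate_transplants(spec, truth)
    idx = simulate_index(spec, truth, outcome=repop)
    colonies = simulate_colonies(spec)
    return idx, records, colonies


def simulate_cell_truth(
    spec: SimSpec,
    n_cells: int,
    strategy: str = "HSC1",
    prefix: str = "SEQ",
) -> pd.Series:
    """Latent MolO flags for an auxiliary cohort sorted with one strategy."""
    stream = 51 + sum(prefix.encode()) % 1000  # stable across processes
    rng = spec._rng(stream)
    p = spec.repop_prob[spec.strategies.index(strategy)]
    ids = pd.Index([f"{prefix}_c{i:04d}" for i in range(n_cells)], name="cell_id")
    return pd.Series(rng.random(n_cells) < p, index=ids, name="molo")
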