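"""Domain containers, tabular readers/writers, configuration and run manifests.

All tables are plain delimited text (tab by default, comma for ``.csv``),
cells-in-rows on disk except for count matrices, which follow the community
genes-by-cells convention.  Floats are written with 17 significant digits so
that write-then-read round-trips are bit-exact for IEEE doubles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("molo")

#: value written to disk for a qPCR reaction that did not reach threshold
UNDETECTED_SENTINEL = "999"

#: format preserving float64 exactly through text round-trips
FLOAT_FMT = "%.17g"


def configure_logging(level: str = "INFO") -> None:
    """Route package logging to stderr at the given level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


def _sep_for(path: Path | str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class CtMatrix:
    """Raw single-cell qPCR cycle-threshold values.

    ``values`` is cells x assays (lower Ct = more transcript); ``detected``
    is a boolean mask of the same shape; undetected entries carry
    ``detected=False`` and the limit-of-detection Ct as a sentinel value.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    cell_meta: pd.DataFrame  # index cell_id: population_label, well_id
    assay_meta: pd.DataFrame  # index gene_name: is_housekeeper
    lod_ct: float = 40.0

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell_id(s): {dupes}")
        if self.values.shape != self.detected.shape:
            raise ValueError("values and detected must have identical shape")
        if not self.assay_meta["is_housekeeper"].any():
            raise ValueError("at least one assay must be flagged as housekeeper")
        if not self.values.index.equals(self.cell_meta.index):
            raise ValueError("cell_meta index must match values index")
        if not self.values.columns.equals(pd.Index(self.assay_meta.index)):
            raise ValueError("assay_meta index must match values columns")

    @property
    def housekeepers(self) -> list[str]:
        return list(self.assay_meta.index[self.assay_meta["is_housekeeper"]])

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]


@dataclass
class CountsMatrix:
    """Integer gene-by-cell count matrix with spike-in rows flagged."""

    counts: pd.DataFrame  # genes x cells, int
    gene_meta: pd.DataFrame  # index gene_id: is_spikein
    cell_meta: pd.DataFrame  # index cell_id: qc_pass

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(f"negative count at ({i}, {j})")

    @property
    def spikein_genes(self) -> list[str]:
        return list(self.gene_meta.index[self.gene_meta["is_spikein"]])

    @property
    def bio_genes(self) -> list[str]:
        return list(self.gene_meta.index[~self.gene_meta["is_spikein"]])


@dataclass
class IndexSortTable:
    """Per-well index-sort channel intensities with optional outcome."""

    channels: pd.DataFrame  # index cell_id, one column per instrument channel
    batch_id: pd.Series
    outcome: pd.Series | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.channels.isna().any().any():
            raise ValueError("channel intensities must be complete after loading")
        if not self.channels.index.equals(self.batch_id.index):
            raise ValueError("batch_id index must match channels index")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels.columns)


@dataclass
class TransplantRecord:
    """Per-mouse donor/recipient cell counts by week and lineage."""

    mouse_id: str
    dose: int
    measurements: pd.DataFrame  # columns: week, lineage, donor, recipient

    def __post_init__(self) -> None:
        if self.dose < 1:
            raise ValueError(f"dose must be >= 1, got {self.dose} for {self.mouse_id}")
        m = self.measurements
        if ((m["donor"] + m["recipient"]) <= 0).any():
            raise ValueError(f"donor + recipient must be > 0 for every reported entry ({self.mouse_id})")
        for lineage, grp in m.groupby("lineage"):
            wk = grp["week"].to_numpy()
            if not np.all(np.diff(wk) > 0):
                raise ValueError(f"weeks must be strictly increasing per lineage ({self.mouse_id}/{lineage})")

    def donor_pct(self, week: float, lineage: str) -> float | None:
        m = self.measurements
        row = m[(m["week"] == week) & (m["lineage"] == lineage)]
        if row.empty:
            return None
        d, r = float(row["donor"].iloc[0]), float(row["recipient"].iloc[0])
        return 100.0 * d / (d + r)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CT_META_COLS = ("cell_id", "population_label", "well_id")


def read_ct_table(
    path: str | Path,
    housekeepers: Sequence[str],
    lod_ct: float = 40.0,
) -> CtMatrix:
    """Load a Fluidigm-style Ct table (cells in rows, assays in columns).

    Undetected or failed reactions — entries of ``999``, blanks, or any Ct at
    or beyond ``lod_ct`` — are flagged ``detected=False`` and set to
    ``lod_ct`` so the matrix stays dense with undetected = least expressed.
    The population label is taken from a ``population_label`` (or
    ``population``) column when present.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "cell_id" not in raw.columns:
        raw = raw.rename(columns={raw.columns[0]: "cell_id"})
    if "population" in raw.columns and "population_label" not in raw.columns:
        raw = raw.rename(columns={"population": "population_label"})
    if raw["cell_id"].duplicated().any():
        dupes = raw.loc[raw["cell_id"].duplicated(), "cell_id"].unique().tolist()
        raise ValueError(f"duplicate cell_id(s): {dupes}")
    raw = raw.set_index("cell_id")

    meta_cols = [c for c in ("population_label", "well_id") if c in raw.columns]
    assay_cols = [c for c in raw.columns if c not in meta_cols]
    for hk in housekeepers:
        if hk not in assay_cols:
            raise ValueError(f"housekeeper column missing from table: {hk!r}")

    def _parse(x):  # Python's float() is correctly rounded; to_numeric is not
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    vals = raw[assay_cols].map(_parse)
    undet = vals.isna() | (vals >= lod_ct)
    values = vals.mask(undet, lod_ct).astype(float)
    detected = ~undet

    cell_meta = pd.DataFrame(index=raw.index)
    cell_meta["population_label"] = raw["population_label"] if "population_label" in meta_cols else "unknown"
    cell_meta["well_id"] = raw["well_id"] if "well_id" in meta_cols else raw.index
    assay_meta = pd.DataFrame(
        {"is_housekeeper": [c in set(housekeepers) for c in assay_cols]},
        index=pd.Index(assay_cols, name="gene_name"),
    )
    return CtMatrix(values, detected, cell_meta, assay_meta, lod_ct=lod_ct)


def write_ct_table(ct: CtMatrix, path: str | Path) -> None:
    """Write a Ct table; undetected entries are emitted as the 999 sentinel."""
    path = Path(path)
    out = ct.values.map(lambda v: FLOAT_FMT % v)
    out = out.where(ct.detected, UNDETECTED_SENTINEL)
    out.insert(0, "well_id", ct.cell_meta["well_id"])
    out.insert(0, "population_label", ct.cell_meta["population_label"])
    out.index.name = "cell_id"
    out.to_csv(path, sep=_sep_for(path))


def read_counts(path: str | Path, spikein_prefix: str = "ERCC-") -> CountsMatrix:
    """Load a genes x cells count matrix from TSV or MatrixMarket.

    A MatrixMarket file ``x.mtx`` needs sidecars ``x.mtx.rows`` and
    ``x.mtx.cols`` (one name per line).  Genes whose id starts with
    ``spikein_prefix`` are flagged as spike-ins.  Negative or non-integer
    entries are a hard error naming the offending (row, column).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        genes = Path(str(path) + ".rows").read_text().split()
        cells = Path(str(path) + ".cols").read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=cells)
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    arr = df.to_numpy()
    bad = ~np.isfinite(arr) | (arr != np.floor(arr)) | (arr < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"invalid count {arr[i, j]!r} at ({i}, {j}): counts must be non-negative integers")
    df = df.astype(np.int64)
    df.index.name = "gene_id"
    gene_meta = pd.DataFrame(
        {"is_spikein": [str(g).startswith(spikein_prefix) for g in df.index]}, index=df.index
    )
    cell_meta = pd.DataFrame({"qc_pass": True}, index=pd.Index(df.columns, name="cell_id"))
    return CountsMatrix(df, gene_meta, cell_meta)


def write_counts(cm: CountsMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep=_sep_for(path))


def read_index_table(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
) -> IndexSortTable:
    """Load an index-sort table; rows with missing channel values are dropped
    (and counted in ``n_dropped``)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if "cell_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "cell_id"})
    df = df.set_index("cell_id")
    meta = [c for c in ("batch_id", "outcome") if c in df.columns]
    if channel_names is None:
        channel_names = [c for c in df.columns if c not in meta]
    chan = df[list(channel_names)].apply(pd.to_numeric, errors="coerce")
    keep = ~chan.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d index rows with missing channel values", n_dropped)
    chan = chan[keep]
    batch = df.loc[keep, "batch_id"] if "batch_id" in meta else pd.Series("batch0", index=chan.index, name="batch_id")
    outcome = df.loc[keep, "outcome"] if "outcome" in meta else None
    return IndexSortTable(chan, batch, outcome, n_dropped=n_dropped)


def write_index_table(idx: IndexSortTable, path: str | Path) -> None:
    out = idx.channels.copy()
    out.insert(0, "batch_id", idx.batch_id)
    if idx.outcome is not None:
        out["outcome"] = idx.outcome
    out.index.name = "cell_id"
    out.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT)


def read_transplant_table(path: str | Path) -> list[TransplantRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    records = []
    for mouse_id, grp in df.groupby("mouse_id", sort=False):
        dose = int(grp["dose"].iloc[0])
        meas = grp[["week", "lineage", "donor", "recipient"]].reset_index(drop=True)
        records.append(TransplantRecord(str(mouse_id), dose, meas))
    return records


def write_transplant_table(records: Iterable[TransplantRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        m = rec.measurements.copy()
        m.insert(0, "dose", rec.dose)
        m.insert(0, "mouse_id", rec.mouse_id)
        rows.append(m)
    pd.concat(rows, ignore_index=True).to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FMT)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Uniform TSV writer for stage outputs (full float precision)."""
    df.to_csv(path, sep=_sep_for(path), index=index, float_format=FLOAT_FMT)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), index_col=index_col, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class TsneSettings:
    perplexity: float = 30.0
    init_dims: int = 30


@dataclass
class MoloSettings:
    k: int = 20
    alpha: float = 0.95
    n_perm: int = 1000
    fdr: float = 0.05
    weights: dict[str, float] | None = None  # strategy -> repopulation probability


@dataclass
class HvgSettings:
    fdr: float = 0.1
    min_spikein_mean: float = 10.0
    mode: str = "chi2"  # or "exceed"


@dataclass
class ClassifierSettings:
    n_trees: int = 1000
    folds: int = 10
    train_strategy: str = "HSC1"


@dataclass
class Thresholds:
    chimerism_pct: float = 1.0
    subtype_high: float = 2.0
    subtype_low: float = 0.25


@dataclass
class PipelineConfig:
    """All tunable settings, fanned out per stage from a single seed."""

    seed: int = 0
    tsne: TsneSettings = field(default_factory=TsneSettings)
    molo: MoloSettings = field(default_factory=MoloSettings)
    hvg: HvgSettings = field(default_factory=HvgSettings)
    classifier: ClassifierSettings = field(default_factory=ClassifierSettings)
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: dict = field(default_factory=dict)  # SimSpec overrides

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tsne.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if not (0 < self.molo.alpha <= 1):
            raise ValueError("molo.alpha must lie in (0, 1]")
        if self.molo.k < 1 or self.molo.n_perm < 1:
            raise ValueError("molo.k and molo.n_perm must be >= 1")
        if not (0 < self.hvg.fdr < 1) or not (0 < self.molo.fdr < 1):
            raise ValueError("FDR settings must lie in (0, 1)")
        if self.hvg.mode not in ("chi2", "exceed"):
            raise ValueError("hvg.mode must be 'chi2' or 'exceed'")
        if self.classifier.folds < 2 or self.classifier.n_trees < 1:
            raise ValueError("classifier.folds >= 2 and n_trees >= 1 required")
        if self.thresholds.chimerism_pct < 0:
            raise ValueError("chimerism threshold must be non-negative")
        if not (self.thresholds.subtype_low < self.thresholds.subtype_high):
            raise ValueError("subtype_low must be below subtype_high")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "tsne", "molo", "hvg", "classifier", "thresholds",
            ):
                sub = {"tsne": TsneSettings, "molo": MoloSettings, "hvg": HvgSettings,
                       "classifier": ClassifierSettings, "thresholds": Thresholds}[f.name]
                v = sub(**v) if isinstance(v, Mapping) else v
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed from the single config seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


class RunManifest:
    """JSON record of the stages executed in an output directory.

    Deliberately timestamp-free so that identical config + seed reproduce the
    manifest byte for byte.
    """

    def __init__(self, out_dir: str | Path):
        self.path = Path(out_dir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"stages": []}

    def add_stage(
        self,
        name: str,
        inputs: Sequence[str],
        outputs: Sequence[str],
        seed: int,
        config_hash: str,
    ) -> None:
        entry = {
            "stage": name,
            "inputs": sorted(str(i) for i in inputs),
            "outputs": sorted(str(o) for o in outputs),
            "seed": seed,
            "config_hash": config_hash,
        }
        self.data["stages"] = [s for s in self.data["stages"] if s["stage"] != name] + [entry]
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")

    @property
    def stage_names(self) -> list[str]:
        return [s["stage"] for s in self.data["stages"]]
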