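"""Random-forest MolO scoring, transferable from the qPCR panel to RNA-seq.

The classifier is trained on one sorting strategy's ΔCt profiles labeled
MolO/NoMO, restricted to the genes that are both on the qPCR panel and
variable above technical noise in the RNA-seq data.  Cross-platform scale
alignment: values are first put on a common "expression" orientation
(ΔCt is negated, log-normalized counts are used as-is) and then each gene
is z-scored within its own platform.  The MolO score of a cell is the
fraction of trees voting MolO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .molo_finder import MolOAssignment
from .qpcr_panel import DeltaCtMatrix

PLATFORMS = ("qpcr", "rnaseq")


def platform_features(values: pd.DataFrame, platform: str) -> pd.DataFrame:
    """Orient to the expression scale and z-score each gene within platform."""
    if platform not in PLATFORMS:
        raise ValueError(f"unknown platform {platform!r}; expected one of {PLATFORMS}")
    expr = -values if platform == "qpcr" else values
    mu = expr.mean(axis=0)
    sd = expr.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (expr - mu) / sd


@dataclass
class MolOClassifier:
    model: RandomForestClassifier
    features: list[str]
    train_platform: str
    seed: int

    @property
    def importances(self) -> pd.Series:
        imp = pd.Series(self.model.feature_importances_, index=self.features, name="importance")
        return imp.sort_values(ascending=False)


@dataclass
class MolOScore:
    scores: pd.Series  # per cell, in [0, 1]
    platform: str
    features: list[str]

    def __post_init__(self) -> None:
        s = self.scores
        if ((s < 0) | (s > 1)).any():
            raise ValueError("MolO scores must lie in [0, 1]")


def train_molo_classifier(
    dct: DeltaCtMatrix,
    assign: MolOAssignment,
    genes: list[str],
    n_trees: int = 1000,
    seed: int = 0,
    strategy: str | None = None,
) -> MolOClassifier:
    """Fit a random forest on MolO/NoMO-labeled ΔCt profiles.

    ``genes`` is the shared variable panel; ``strategy`` restricts training
    to one sorting strategy's cells (the strategy with transferable RNA-seq
    data).  Both classes must be present.
    """
    if not genes:
        raise ValueError("feature gene list is empty")
    missing = [g for g in genes if g not in dct.values.columns]
    if missing:
        raise KeyError(f"genes not in ΔCt panel: {missing}")
    cells = dct.values.index
    if strategy is not None:
        cells = cells[dct.populations.loc[cells] == strategy]
    labeled = assign.table.loc[assign.table["label"].isin(["MolO", "NoMO"])].index
    cells = cells.intersection(labeled)
    y = assign.table.loc[cells, "label"]
    if y.nunique() < 2:
        raise ValueError(f"training set has a single class ({y.unique().tolist()}); cannot fit")
    x = platform_features(dct.values.loc[cells, list(genes)], "qpcr")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        class_weight="balanced",
    )
    rf.fit(x.to_numpy(), (y == "MolO").to_numpy())
    return MolOClassifier(model=rf, features=list(genes), train_platform="qpcr", seed=seed)


@dataclass
class CVResult:
    fold_accuracy: list[float]
    mean_accuracy: float
    sd_accuracy: float
    predictions: pd.DataFrame  # index cell: fold, true, predicted

    def recount_accuracy(self) -> float:
        """Accuracy recomputed from the persisted per-fold predictions."""
        p = self.predictions
        return float((p["true"] == p["predicted"]).mean())


def crossvalidate(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = 1000,
) -> CVResult:
    """Stratified k-fold cross-validated accuracy of the forest.

    Fold assignment is deterministic given the seed.  Raises if any class
    has fewer members than folds (a fold would miss the class).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = labels.loc[features.index]
    counts = y.value_counts()
    if (counts < folds).any():
        raise ValueError(f"class counts {counts.to_dict()} too small for {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    x = features.to_numpy(dtype=float)
    yv = y.to_numpy()
    accs, rows = [], []
    for fold, (tr, te) in enumerate(skf.split(x, yv)):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, class_weight="balanced")
        rf.fit(x[tr], yv[tr])
        pred = rf.predict(x[te])
        accs.append(float((pred == yv[te]).mean()))
        for i, cell in enumerate(features.index[te]):
            rows.append({"cell_id": cell, "fold": fold, "true": yv[te][i], "predicted": pred[i]})
    preds = pd.DataFrame(rows).set_index("cell_id")
    return CVResult(
        fold_accuracy=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)),
        predictions=preds,
    )


def score_cells(
    clf: MolOClassifier,
    features: pd.DataFrame,
    platform: str,
) -> MolOScore:
    """MolO class probability per cell over the classifier's feature panel.

    Features are matched by name (column order is irrelevant); a missing
    feature is a hard error naming it.
    """
    missing = [g for g in clf.features if g not in features.columns]
    if missing:
        raise KeyError(f"missing feature(s) for scoring: {missing}")
    x = platform_features(features[clf.features], platform)
    proba = clf.model.predict_proba(x.to_numpy())
    molo_col = list(clf.model.classes_).index(True)
    scores = pd.Series(proba[:, molo_col], index=features.index, name="molo_score")
    return MolOScore(scores=scores, platform=platform, features=list(clf.features))
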