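"""Seed-controlled 2D t-SNE maps for the MolO search and SuMO linkage.

Settings follow the reference implementation's defaults: perplexity 30 with
PCA pre-reduction to min(30, n_features) dimensions.  Coordinates are in
arbitrary units; everything downstream consumes only the coordinates plus
per-cell metadata, never the raw features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE


@dataclass
class Embedding2D:
    coords: pd.DataFrame  # index cell_id, columns x, y
    input_kind: str  # "qpcr_genes" or "surface_markers"
    perplexity: float
    seed: int
    init_dims: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords[["x", "y"]].to_numpy())):
            raise ValueError("embedding coordinates must be finite")

    @property
    def xy(self) -> np.ndarray:
        return self.coords[["x", "y"]].to_numpy()


def embed_tsne(
    features: pd.DataFrame,
    perplexity: float = 30.0,
    seed: int = 0,
    init_dims: int = 30,
    input_kind: str = "qpcr_genes",
) -> Embedding2D:
    """Deterministic t-SNE of a cells x features table.

    Feature columns are sorted by name first, so the map is invariant to
    column order.  Requires ``n_cells > 3 * perplexity`` (the embedding is
    unstable below that) and complete, finite inputs.
    """
    if isinstance(features, pd.DataFrame):
        features = features[sorted(features.columns, key=str)]
        index = features.index
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite with no missing values")
    n = x.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} cells; "
            f"use perplexity < {n / 3:.1f}"
        )

    dims = min(init_dims, x.shape[1], n)
    if x.shape[1] > dims:
        x = PCA(n_components=dims, random_state=seed).fit_transform(x)

    # the exact gradient keeps duplicate rows coincident; Barnes-Hut's tree
    # approximation can split them, so reserve it for large inputs
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        learning_rate="auto",
        method="exact" if n < 300 else "barnes_hut",
    ).fit_transform(x)
    df = pd.DataFrame(coords, index=index, columns=["x", "y"])
    return Embedding2D(df, input_kind=input_kind, perplexity=perplexity, seed=seed, init_dims=init_dims)
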