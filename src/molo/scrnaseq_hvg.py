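"""Count normalization, spike-in noise calibration, variable genes, PCA and
score-correlated gene signatures.

Size factors follow the median-of-ratios recipe (rescaled to geometric mean
one).  Technical noise is calibrated on ERCC spike-ins by regressing their
squared coefficient of variation on 1/mean (gamma-family GLM, identity
link), giving CV²_tech(μ) = a1/μ + a0.  A gene is variable when its CV²
significantly exceeds that curve — by default via a chi-square exceedance
test on (n−1)·CV²/CV²_tech with BH control, with plain exceedance exposed
as an alternative mode.  Expression for PCA and correlations is
log2(count/size_factor + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .io_core import CountsMatrix, logger
from .stats_utils import benjamini_hochberg, spearman_test


@dataclass
class SizeFactors:
    factors: pd.Series  # per cell, positive, geometric mean 1
    method: str = "median_of_ratios"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class NoiseFit:
    """CV²_tech(μ) = a1 / μ + a0 fitted on spike-ins."""

    a0: float
    a1: float
    se_a0: float
    se_a1: float
    min_mean: float
    n_spikeins: int

    def expected_cv2(self, mean: np.ndarray) -> np.ndarray:
        return self.a1 / np.asarray(mean, dtype=float) + self.a0

    def to_dict(self) -> dict:
        return {
            "a0": self.a0, "a1": self.a1, "se_a0": self.se_a0,
            "se_a1": self.se_a1, "min_mean": self.min_mean,
            "n_spikeins": self.n_spikeins,
        }


def size_factors(cm: CountsMatrix) -> SizeFactors:
    """Median-of-ratios size factors over genes expressed in every cell.

    If no gene is nonzero in all cells the estimate falls back to
    library-size ratios (warned).  Factors are rescaled to geometric mean 1.
    """
    counts = cm.counts.to_numpy(dtype=float)
    usable = (counts > 0).all(axis=1)
    if usable.any():
        sub = counts[usable]
        geo = np.exp(np.log(sub).mean(axis=1))
        s = np.median(sub / geo[:, None], axis=0)
        method = "median_of_ratios"
    else:
        logger.warning("size_factors: no gene nonzero in all cells; using library-size ratios")
        lib = counts.sum(axis=0)
        s = lib / np.exp(np.log(lib).mean())
        method = "library_size"
    s = s / np.exp(np.log(s).mean())
    return SizeFactors(pd.Series(s, index=cm.counts.columns, name="size_factor"), method)


def normalized_expression(cm: CountsMatrix, sf: SizeFactors, log: bool = True) -> pd.DataFrame:
    """Cells x genes expression: count / size factor, optionally log2(x+1)."""
    norm = cm.counts.div(sf.factors, axis=1)
    expr = np.log2(norm + 1.0) if log else norm
    return expr.T


def _mean_cv2(norm: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = var / mu**2
    return mu, cv2


def fit_technical_noise(
    cm: CountsMatrix,
    sf: SizeFactors,
    min_mean: float = 10.0,
) -> NoiseFit:
    """Fit CV² = a0 + a1/μ on spike-ins with normalized mean >= min_mean."""
    spikes = cm.counts.loc[cm.gene_meta["is_spikein"]]
    if spikes.empty:
        raise ValueError("no spike-in genes flagged; cannot fit technical noise")
    norm = spikes.div(sf.factors, axis=1)
    mu, cv2 = _mean_cv2(norm)
    keep = (mu >= min_mean) & np.isfinite(cv2) & (cv2 > 0)
    if keep.sum() < 10:
        raise ValueError(
            f"only {int(keep.sum())} spike-ins with mean >= {min_mean}; lower min_mean"
        )
    y = cv2[keep].to_numpy()
    X = sm.add_constant(1.0 / mu[keep].to_numpy())
    start = np.linalg.lstsq(X, y, rcond=None)[0]
    start = np.maximum(start, [1e-6, 1e-6])
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Identity()))
    res = model.fit(start_params=start)
    a0, a1 = float(res.params[0]), float(res.params[1])
    se_a0, se_a1 = float(res.bse[0]), float(res.bse[1])
    if a1 <= 0:
        logger.warning("fit_technical_noise: non-positive a1 (%.3g); fit is suspect", a1)
    return NoiseFit(a0=a0, a1=a1, se_a0=se_a0, se_a1=se_a1, min_mean=min_mean, n_spikeins=int(keep.sum()))


def call_variable_genes(
    cm: CountsMatrix,
    sf: SizeFactors,
    fit: NoiseFit,
    fdr: float = 0.1,
    mode: str = "chi2",
) -> pd.DataFrame:
    """Flag biological genes whose variability exceeds the technical curve.

    mode="chi2": (n−1)·CV²/CV²_tech against the chi-square(n−1) upper tail,
    BH at ``fdr``; variable = significant AND above the curve.
    mode="exceed": plain exceedance of the fitted curve (no test).
    Zero-variance genes get p = 1 and are never variable.
    """
    bio = cm.counts.loc[~cm.gene_meta["is_spikein"]]
    norm = bio.div(sf.factors, axis=1)
    mu, cv2 = _mean_cv2(norm)
    n = bio.shape[1]
    expected = pd.Series(fit.expected_cv2(mu.to_numpy()), index=mu.index)
    cv2_filled = cv2.fillna(0.0)
    stat = (n - 1) * cv2_filled / expected
    p = pd.Series(chi2.sf(stat, df=n - 1), index=mu.index)
    p[cv2_filled <= 0] = 1.0
    q = pd.Series(benjamini_hochberg(p.to_numpy()), index=p.index)
    above = cv2_filled > expected
    if mode == "chi2":
        variable = (q <= fdr) & above
    elif mode == "exceed":
        variable = above
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(
        {"mean": mu, "cv2": cv2_filled, "expected_cv2": expected,
         "statistic": stat, "p": p, "q": q, "variable": variable}
    )
    out.index.name = "gene_id"
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame  # cells x components
    loadings: pd.DataFrame  # genes x components, orthonormal columns
    variance_ratio: np.ndarray


def pca_cells(expr: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Centered PCA of a cells x genes expression table."""
    if expr.shape[0] < 3:
        raise ValueError("need >= 3 cells for PCA")
    from sklearn.decomposition import PCA

    k = n_components or min(expr.shape[0] - 1, expr.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(expr.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=expr.columns, columns=comp_names),
        variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class GeneSignature:
    table: pd.DataFrame  # index gene: rho, p, q, direction, significant
    n_excluded: int
    fdr: float

    @property
    def positive(self) -> pd.Index:
        t = self.table
        return t.index[t["significant"] & (t["rho"] > 0)]

    @property
    def negative(self) -> pd.Index:
        t = self.table
        return t.index[t["significant"] & (t["rho"] < 0)]


def correlate_genes_with_score(
    expr: pd.DataFrame,
    score: pd.Series,
    fdr: float = 0.1,
) -> GeneSignature:
    """Spearman correlation of every gene with a per-cell score, BH-corrected.

    Positively and negatively significant genes form the score's signature;
    constant genes are excluded (counted).  Rows are ranked by rho.
    """
    common = expr.index.intersection(score.index)
    if len(common) < 5:
        raise ValueError("need >= 5 scored cells")
    expr = expr.loc[common]
    s = score.loc[common].to_numpy(dtype=float)
    rows = []
    n_excluded = 0
    for g in expr.columns:
        x = expr[g].to_numpy(dtype=float)
        rho, p = spearman_test(x, s)
        if np.isnan(rho):
            n_excluded += 1
            continue
        rows.append({"gene": g, "rho": rho, "p": p})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["direction"] = np.where(out["rho"] > 0, "positive", "negative")
    out["significant"] = out["q"] <= fdr
    out = out.sort_values("rho", ascending=False)
    return GeneSignature(out, n_excluded=n_excluded, fdr=fdr)
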