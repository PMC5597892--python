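"""PCA and hierarchical clustering for heat-map-ready orderings.

PCA treats samples as observations and genes as variables (samples are the
plotted points), centres columns and does not scale them by default —
mirroring ``prcomp``'s defaults.  Clustering uses Spearman-correlation
distance (1 - rho, average ranks for ties) with average linkage (UPGMA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .io import ValidationError
from .quant import log2_median_center


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # samples x components
    proportion_variance: np.ndarray  # fraction per component, sums to 1
    loadings: pd.DataFrame  # genes x components


@dataclass(frozen=True)
class Dendrogram:
    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    leaf_order: list[str]
    labels: list[str]


def pca(expr: pd.DataFrame, scale: bool = False) -> PcaResult:
    """Principal components of an expression matrix (genes x samples).

    Samples are observations; each gene column of the transposed matrix is
    mean-centred (and optionally unit-scaled) before the SVD.  The variance
    proportion of component k is sigma_k^2 / sum sigma^2.
    """
    x = expr.T.to_numpy(dtype=float)  # samples x genes
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 genes")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError("cannot scale: constant gene column")
        x = x / sd
    if np.allclose(x, 0):
        raise ValidationError("constant matrix has no variance to decompose")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    prop = s**2 / np.sum(s**2)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=expr.columns, columns=comp),
        proportion_variance=prop,
        loadings=pd.DataFrame(vt.T, index=expr.index, columns=comp),
    )


def spearman_distance(rows: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Spearman rho between rows; range [0, 2]."""
    x = rows.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValidationError("need >= 2 columns per row")
    if np.any(x.std(axis=1) == 0):
        bad = list(rows.index[np.std(x, axis=1) == 0])
        raise ValidationError(f"constant row(s) have undefined correlation: {bad[:5]}")
    rho = spearmanr(x, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-row case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=rows.index, columns=rows.index)


def average_linkage_cluster(d: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram from a symmetric zero-diagonal distance matrix."""
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValidationError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    merges = linkage(squareform(arr, checks=False), method="average")
    labels = [str(i) for i in d.index]
    order = [labels[i] for i in leaves_list(merges)]
    return Dendrogram(merges=merges, leaf_order=order, labels=labels)


def heatmap_export(
    expr: pd.DataFrame,
    gene_dendrogram: Dendrogram,
    sample_order: list[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Log2 median-centred matrix with rows in dendrogram leaf order."""
    centred = log2_median_center(expr, pseudocount=pseudocount)
    cols = sample_order if sample_order is not None else list(centred.columns)
    return centred.loc[gene_dendrogram.leaf_order, cols]
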