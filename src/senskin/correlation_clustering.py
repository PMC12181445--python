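"""Inter-gene correlation structure of a signature on pseudobulk expression.

Pipeline stage mirroring a common signature-characterization recipe: check
per-gene skewness and log-transform if any gene is strongly right-skewed,
standardize each gene, compute the gene-gene correlation matrix, then cut a
complete-linkage dendrogram (distance = 1 - r) into k clusters of
co-regulated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .preprocess import Pseudobulk

logger = logging.getLogger(__name__)


@dataclass
class GeneClustering:
    """Correlation matrix, merge history and a k-cluster cut for a gene panel.

    Cluster ids run 1..k in order of first appearance along the dendrogram
    leaf order, so each cluster is a contiguous block in ``dendrogram_order``.
    """

    genes: list[str]
    corr: pd.DataFrame
    linkage: np.ndarray
    k: int
    assignment: pd.Series  # gene -> cluster id in 1..k
    dendrogram_order: list[str]


def skewness(x, estimator: str = "adjusted") -> float:
    """Sample skewness of a vector.

    ``estimator="adjusted"`` is the adjusted Fisher-Pearson statistic
    G1 = g1 * sqrt(n(n-1))/(n-2) (the common default in statistical
    software); ``"g1"`` is the uncorrected moment ratio m3 / m2^1.5.
    Vectors with fewer than 3 values or zero variance return 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        logger.warning("skewness undefined (n < 3 or zero variance); returning 0")
        return 0.0
    if estimator not in ("adjusted", "g1"):
        raise ValueError("estimator must be 'adjusted' or 'g1'")
    return float(stats.skew(x, bias=(estimator == "g1")))


def gated_log_transform(
    pb: Pseudobulk,
    threshold: float = 2.0,
    mode: str = "global",
    estimator: str = "adjusted",
) -> tuple[Pseudobulk, list[str]]:
    """ln(1+x)-transform skewed pseudobulk expression.

    In ``"global"`` mode (the default reading of the recipe) the whole matrix
    is log-transformed as soon as *any* gene's skewness exceeds ``threshold``;
    ``"per_gene"`` transforms only the offending genes. Returns the (possibly
    transformed) pseudobulk and the list of genes that exceeded the threshold.
    """
    if mode not in ("global", "per_gene"):
        raise ValueError("mode must be 'global' or 'per_gene'")
    values = pb.values
    if (values.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    skews = values.apply(lambda row: skewness(row.to_numpy(), estimator), axis=1)
    triggered = skews.index[skews > threshold].tolist()
    if not triggered:
        return pb, []
    out = values.copy()
    if mode == "global":
        out = np.log1p(out)
    else:
        out.loc[triggered] = np.log1p(out.loc[triggered])
    return Pseudobulk(values=out, group_meta=pb.group_meta, groupby=pb.groupby), triggered


def gene_correlation(
    pb: Pseudobulk,
    genes: list[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Gene-gene correlation across pseudobulk groups.

    Rows are standardized per gene before Pearson correlation (``method``
    may also be ``"spearman"``). Requires at least 3 group columns.
    Zero-variance genes get correlation 0 with every other gene and 1 with
    themselves, and are flagged with a warning.
    """
    values = pb.values if genes is None else pb.values.loc[genes]
    if values.shape[1] < 3:
        raise ValueError("need at least 3 pseudobulk groups to correlate genes")
    X = values.to_numpy(dtype=float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    sd = X.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance gene(s); their correlations set to 0",
                       int(flat.sum()))
    Xs = X - X.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xs = Xs / (sd * np.sqrt(X.shape[1] - 1))[:, None]
    Xs[flat] = 0.0
    corr = np.clip(Xs @ Xs.T, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def complete_linkage(corr: pd.DataFrame, k: int = 5) -> GeneClustering:
    """Complete-linkage agglomeration on distance 1 - r, cut into k clusters.

    Merge order on exact ties follows the scipy implementation (deterministic
    for a given gene order); cluster labels are renumbered 1..k by dendrogram
    position so reports are stable.
    """
    genes = list(corr.index)
    n = len(genes)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    if n == 1:
        Z = np.empty((0, 4))
        order = [0]
        labels = np.array([1])
    else:
        Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
        order = hierarchy.leaves_list(Z).tolist()
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # renumber clusters by first appearance along the leaf order
    remap: dict[int, int] = {}
    for leaf in order:
        remap.setdefault(labels[leaf], len(remap) + 1)
    assignment = pd.Series([remap[l] for l in labels], index=genes, name="cluster")
    return GeneClustering(
        genes=genes,
        corr=corr,
        linkage=Z,
        k=int(assignment.max()),
        assignment=assignment,
        dendrogram_order=[genes[i] for i in order],
    )


def plot_heatmap(clustering: GeneClustering, path) -> None:
    """Write a clustered correlation heatmap (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = clustering.dendrogram_order
    mat = clustering.corr.loc[order, order]
    fig, axis = plt.subplots(figsize=(8, 8))
    im = axis.imshow(mat, cmap="RdBu_r", vmin=-1, vmax=1)
    axis.set_xticks([])
    axis.set_yticks([])
    fig.colorbar(im, ax=axis, label="Pearson r")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
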