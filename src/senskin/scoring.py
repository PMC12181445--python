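"""Per-cell composite senescence score and per-cell-type condition contrasts.

The composite score of a cell is the mean z-score over the signature's
up-genes minus the mean z-score over its down-genes:

    score(c) = (1/|U|) * sum_{g in U} z(c, g)  -  (1/|D|) * sum_{g in D} z(c, g)

where U and D are the up- and down-gene subsets actually present in the
matrix. Signature genes missing from the data are excluded and the divisors
shrink accordingly (the counts used are reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geneset import SignedGeneSet

logger = logging.getLogger(__name__)

# below this per-group size (and with no ties) the rank test is exact
EXACT_MAX_N = 25


@dataclass
class ScoreTable:
    """Per-cell composite scores with the cell metadata carried through."""

    scores: pd.DataFrame  # columns: score + original cell metadata
    set_name: str
    n_up_used: int
    n_down_used: int


@dataclass
class ContrastResult:
    """One cell type's two-condition score comparison."""

    cell_type: str
    n_cells: dict[str, int]
    median_score: dict[str, float]
    mean_score: dict[str, float]
    direction: str  # "up", "down", "ns", or "insufficient"
    statistic: float
    p_value: float
    p_adjusted: float


def composite_score(z: ad.AnnData, gene_set: SignedGeneSet) -> ScoreTable:
    """Score every cell against a signed gene set on a z-scored matrix."""
    index = {g.casefold(): j for j, g in enumerate(z.var_names)}
    up_idx = [index[g.casefold()] for g in gene_set.up_genes if g.casefold() in index]
    dn_idx = [index[g.casefold()] for g in gene_set.down_genes if g.casefold() in index]
    if not up_idx and not dn_idx:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    n_missing = len(gene_set) - len(up_idx) - len(dn_idx)
    if n_missing:
        logger.warning(
            "%s: %d signature gene(s) absent from the matrix; divisors use the "
            "%d up / %d down genes present",
            gene_set.name, n_missing, len(up_idx), len(dn_idx),
        )
    X = np.asarray(z.X.todense()) if hasattr(z.X, "todense") else np.asarray(z.X)
    score = np.zeros(X.shape[0])
    if up_idx:
        score += X[:, up_idx].mean(axis=1)
    if dn_idx:
        score -= X[:, dn_idx].mean(axis=1)
    elif gene_set.down_genes:
        logger.warning("%s: no down-gene present; down term set to 0", gene_set.name)
    frame = z.obs.copy()
    frame.insert(0, "score", score)
    return ScoreTable(
        scores=frame,
        set_name=gene_set.name,
        n_up_used=len(up_idx),
        n_down_used=len(dn_idx),
    )


def rank_test(
    x: np.ndarray, y: np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Two-sided rank test between two score samples.

    Unpaired data get the Wilcoxon rank-sum (Mann-Whitney U) test — exact
    when both groups have <= 25 observations and no ties, mid-rank normal
    approximation with continuity correction otherwise. ``paired=True``
    switches to the Wilcoxon signed-rank test for matched designs.
    """
    if paired:
        res = stats.wilcoxon(x, y)
        return float(res.statistic), float(res.pvalue)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= EXACT_MAX_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def contrast_by_celltype(
    table: ScoreTable,
    condition_key: str = "condition",
    celltype_key: str = "cell_type",
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    paired: bool = False,
) -> list[ContrastResult]:
    """Test the score difference between the two conditions within each cell type.

    Direction comes from the difference of condition medians; p-values are
    adjusted across cell types (Bonferroni by default, ``adjust="fdr_bh"``
    for Benjamini-Hochberg). Cell types with fewer than 2 cells in either
    condition are flagged ``insufficient`` and not tested.
    """
    df = table.scores
    col = df[condition_key]
    if isinstance(col.dtype, pd.CategoricalDtype):
        conditions = [str(c) for c in col.cat.categories if (col == c).any()]
    else:
        conditions = [str(c) for c in pd.unique(col.astype(str))]
    if len(conditions) != 2:
        raise ValueError(f"expected exactly 2 conditions, found {conditions}")
    # direction is reported for the second condition relative to the first
    c1, c2 = conditions
    results: list[ContrastResult] = []
    pvals, tested = [], []
    for ct in sorted(df[celltype_key].astype(str).unique()):
        sub = df[df[celltype_key].astype(str) == ct]
        x = sub.loc[sub[condition_key].astype(str) == c2, "score"].to_numpy()
        y = sub.loc[sub[condition_key].astype(str) == c1, "score"].to_numpy()
        n_cells = {c1: len(y), c2: len(x)}
        med = {c1: float(np.median(y)) if len(y) else np.nan,
               c2: float(np.median(x)) if len(x) else np.nan}
        mean = {c1: float(np.mean(y)) if len(y) else np.nan,
                c2: float(np.mean(x)) if len(x) else np.nan}
        if len(x) < 2 or len(y) < 2:
            results.append(ContrastResult(ct, n_cells, med, mean, "insufficient",
                                          np.nan, np.nan, np.nan))
            continue
        stat, p = rank_test(x, y, paired=paired)
        results.append(ContrastResult(ct, n_cells, med, mean, "ns", stat, p, np.nan))
        pvals.append(p)
        tested.append(len(results) - 1)
    if pvals:
        reject, p_adj, *_ = multipletests(pvals, alpha=alpha, method=adjust)
        for i, idx in enumerate(tested):
            r = results[idx]
            r.p_adjusted = float(p_adj[i])
            if reject[i]:
                r.direction = "up" if r.median_score[c2] > r.median_score[c1] else "down"
    return results


def contrasts_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Flatten contrast results into a tidy table (one row per cell type)."""
    rows = []
    for r in results:
        conds = list(r.n_cells)
        rows.append(
            {
                "cell_type": r.cell_type,
                **{f"n_{c}": r.n_cells[c] for c in conds},
                **{f"median_{c}": r.median_score[c] for c in conds},
                **{f"mean_{c}": r.mean_score[c] for c in conds},
                "direction": r.direction,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
        )
    return pd.DataFrame(rows)
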