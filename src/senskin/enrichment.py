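"""Phenotype-permutation GSEA, Wilcoxon differential expression, and ORA.

The GSEA engine is self-contained and pins the "default settings" of the
classic tool explicitly:

* ranking metric: signal-to-noise, s2n(g) = (mu_A - mu_B) / (sd_A + sd_B),
  with each sd floored at 0.2 * |mean| (and at 0.2 outright when the mean is
  zero) so near-constant genes cannot dominate the ranking;
* enrichment score: weighted Kolmogorov-Smirnov running sum with hit
  increments |metric|^p (p = 1) normalized over hits and miss decrements
  1/(N - N_hits); ES is the signed maximum deviation from zero;
* null distribution: permutation of the *phenotype* labels (sample
  relabelings), never of genes;
* NES: ES divided by the mean |ES| of same-sign permutation nulls;
  nominal p is the one-sided same-sign fraction with an add-one correction
  (so p is never 0); FDR q follows the sign-stratified procedure comparing
  normalized null and observed NES distributions.

Gene identifiers are used as-is (no probe collapse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geneset import SignedGeneSet

logger = logging.getLogger(__name__)

SD_FLOOR_FRACTION = 0.2
ABS_SD_FLOOR = 0.2


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, metric non-increasing."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("metric must be sorted non-increasing")


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0
    seed: int | None = None


@dataclass
class OraResult:
    pathway: str
    k_overlap: int
    K_pathway: int
    n_query: int
    N_universe: int
    p: float
    fdr: float


def _group_masks(groups, positive: str | None) -> tuple[np.ndarray, str, str]:
    labels = [str(g) for g in groups]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 group labels, found {uniq}")
    pos = uniq[1] if positive is None else str(positive)
    if pos not in uniq:
        raise ValueError(f"positive class {pos!r} not among {uniq}")
    neg = uniq[0] if pos == uniq[1] else uniq[1]
    mask = np.array([l == pos for l in labels])
    return mask, pos, neg


def _s2n_matrix(X: np.ndarray, pos_masks: np.ndarray) -> np.ndarray:
    """Signal-to-noise metric for each column of a batch of label masks.

    X is genes x samples; pos_masks is n_perm x samples boolean. Returns a
    genes x n_perm metric matrix. sds use the n-denominator as in the
    reference tool, then the relative/absolute floors.
    """
    M = pos_masks.astype(float).T  # samples x n_perm
    nA = M.sum(axis=0)
    nB = M.shape[0] - nA
    sumA = X @ M
    sumB = X.sum(axis=1, keepdims=True) - sumA
    meanA, meanB = sumA / nA, sumB / nB
    sqA = (X**2) @ M
    sqB = (X**2).sum(axis=1, keepdims=True) - sqA
    varA = np.maximum(sqA / nA - meanA**2, 0.0)
    varB = np.maximum(sqB / nB - meanB**2, 0.0)
    sdA, sdB = np.sqrt(varA), np.sqrt(varB)
    for sd, mean in ((sdA, meanA), (sdB, meanB)):
        floor = SD_FLOOR_FRACTION * np.abs(mean)
        floor[floor == 0] = ABS_SD_FLOOR
        np.maximum(sd, floor, out=sd)
    return (meanA - meanB) / (sdA + sdB)


def rank_signal_to_noise(
    expr: pd.DataFrame, groups, positive: str | None = None
) -> RankedList:
    """Rank genes by the signal-to-noise metric between two sample groups.

    ``expr`` is genes x samples. ``positive`` names the class whose higher
    expression gives positive metrics (default: the second label in order of
    first appearance). Each group needs at least 3 samples.
    """
    mask, pos, neg = _group_masks(groups, positive)
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError(
            "signal-to-noise needs >= 3 samples per group; use a "
            "ratio-of-classes style metric for smaller designs"
        )
    X = expr.to_numpy(dtype=float)
    s2n = _s2n_matrix(X, mask[None, :])[:, 0]
    order = np.argsort(-s2n, kind="stable")
    return RankedList(
        genes=[expr.index[i] for i in order], metric=s2n[order]
    )


def _es_batch(
    metric: np.ndarray, member: np.ndarray, weight: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """ES for each column of a batch of ranked lists.

    ``metric``: N x P metrics already in ranked (descending) order per
    column; ``member``: N x P boolean set membership in the same order.
    Returns (es, peak_index) per column.
    """
    w = np.abs(metric) ** weight * member
    denom_hit = w.sum(axis=0)
    n_hits = member.sum(axis=0)
    # all-zero hit weights fall back to uniform increments
    uniform = denom_hit == 0
    if uniform.any():
        w[:, uniform] = member[:, uniform]
        denom_hit = np.where(uniform, np.maximum(n_hits, 1), denom_hit)
    n_miss = member.shape[0] - n_hits
    miss_dec = np.divide(
        1.0, n_miss, out=np.zeros_like(denom_hit, dtype=float), where=n_miss > 0
    )
    steps = w / denom_hit - (~member) * miss_dec
    running = np.cumsum(steps, axis=0)
    peak = np.argmax(np.abs(running), axis=0)
    es = running[peak, np.arange(running.shape[1])]
    return es, peak


def enrichment_score(
    ranked: RankedList, set_genes, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of a gene set on a ranked list.

    Returns ``(es, running, leading_edge)`` where ``running`` is the full
    running-sum profile and the leading edge contains the set genes at or
    before the peak (after it for negative ES).
    """
    keys = {str(g).casefold() for g in set_genes}
    member = np.array([g.casefold() in keys for g in ranked.genes])
    if not member.any():
        raise ValueError("no gene of the set is present in the ranked list")
    es_col, peak_col = _es_batch(ranked.metric[:, None], member[:, None], weight)
    es, peak = float(es_col[0]), int(peak_col[0])
    # recompute running profile for reporting
    w = np.abs(ranked.metric) ** weight * member
    denom = w.sum()
    if denom == 0:
        w = member.astype(float)
        denom = w.sum()
    n_miss = len(member) - member.sum()
    miss_dec = 1.0 / n_miss if n_miss else 0.0
    running = np.cumsum(w / denom - (~member) * miss_dec)
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.genes) if member[i] and i <= peak]
    else:
        leading = [g for i, g in enumerate(ranked.genes) if member[i] and i >= peak]
    return es, running, leading


def _normalize_sign_stratified(
    es_obs: np.ndarray, es_null: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NES for observed and null ES, each normalized by the mean |null ES|
    of matching sign for its own set. Sets without same-sign nulls get NaN."""
    n_sets = es_obs.shape[0]
    nes_obs = np.full(n_sets, np.nan)
    nes_null = np.full_like(es_null, np.nan, dtype=float)
    p_nom = np.full(n_sets, np.nan)
    for i in range(n_sets):
        null = es_null[i]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        nes_null[i, null > 0] = null[null > 0] / pos_mean
        nes_null[i, null < 0] = null[null < 0] / neg_mean
        obs = es_obs[i]
        same = null[null > 0] if obs >= 0 else null[null < 0]
        scale = pos_mean if obs >= 0 else neg_mean
        if same.size == 0 or not np.isfinite(scale):
            logger.warning("set %d: no same-sign permutation ES; NES undefined", i)
            continue
        nes_obs[i] = obs / scale
        p_nom[i] = (1 + np.sum(np.abs(same) >= abs(obs))) / (1 + same.size)
    return nes_obs, nes_null, p_nom


def _fdr_sign_stratified(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """GSEA-style FDR q: ratio of the null and observed tail fractions on the
    matching sign side, clipped to [0, 1]."""
    null = nes_null[np.isfinite(nes_null)]
    obs = nes_obs[np.isfinite(nes_obs)]
    q = np.full(nes_obs.shape, np.nan)
    for i, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_side, obs_side = null[null >= 0], obs[obs >= 0]
            num = np.mean(null_side >= nes) if null_side.size else np.nan
            den = np.mean(obs_side >= nes) if obs_side.size else np.nan
        else:
            null_side, obs_side = null[null < 0], obs[obs < 0]
            num = np.mean(null_side <= nes) if null_side.size else np.nan
            den = np.mean(obs_side <= nes) if obs_side.size else np.nan
        if np.isfinite(num) and np.isfinite(den) and den > 0:
            q[i] = min(1.0, num / den)
    return q


def gsea_phenotype(
    expr: pd.DataFrame,
    groups,
    sets: list[SignedGeneSet],
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    positive: str | None = None,
) -> list[GseaResult]:
    """Phenotype-permutation GSEA of signed sets (their up+down unions).

    ``expr`` is genes x samples; ``groups`` the per-sample labels. The null
    is built from ``n_perm`` seeded random relabelings of the samples.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    mask, pos, neg = _group_masks(groups, positive)
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("need >= 3 samples per group")
    X = expr.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    gene_keys = np.array([str(g).casefold() for g in expr.index])

    members = np.stack(
        [np.isin(gene_keys, [g.casefold() for g in s.all_genes]) for s in sets]
    )  # n_sets x n_genes
    if not members.any(axis=1).all():
        bad = [s.name for s, m in zip(sets, members) if not m.any()]
        raise ValueError(f"sets with no gene in the matrix: {bad}")

    rng = np.random.default_rng(seed)
    perm_masks = np.empty((n_perm, n_samples), dtype=bool)
    for j in range(n_perm):
        perm_masks[j] = rng.permutation(mask)

    all_masks = np.vstack([mask[None, :], perm_masks])
    s2n = _s2n_matrix(X, all_masks)  # genes x (1 + n_perm)
    order = np.argsort(-s2n, axis=0, kind="stable")
    metric_sorted = np.take_along_axis(s2n, order, axis=0)

    es_obs = np.empty(len(sets))
    es_null = np.empty((len(sets), n_perm))
    leading: list[list[str]] = []
    genes_arr = np.array(expr.index, dtype=object)
    for i, s in enumerate(sets):
        member_sorted = members[i][order]  # genes x (1+n_perm)
        es_all, peaks = _es_batch(metric_sorted, member_sorted, weight)
        es_obs[i], es_null[i] = es_all[0], es_all[1:]
        peak = int(peaks[0])
        ranked_genes = genes_arr[order[:, 0]]
        hit = member_sorted[:, 0]
        if es_obs[i] >= 0:
            leading.append([g for j, g in enumerate(ranked_genes) if hit[j] and j <= peak])
        else:
            leading.append([g for j, g in enumerate(ranked_genes) if hit[j] and j >= peak])

    nes_obs, nes_null, p_nom = _normalize_sign_stratified(es_obs, es_null)
    fdr_q = _fdr_sign_stratified(nes_obs, nes_null)
    return [
        GseaResult(
            set_name=s.name,
            es=float(es_obs[i]),
            nes=float(nes_obs[i]),
            p_nominal=float(p_nom[i]),
            fdr_q=float(fdr_q[i]),
            leading_edge=leading[i],
            n_perm=n_perm,
            seed=seed,
        )
        for i, s in enumerate(sets)
    ]


def gsea_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "es": r.es,
                "nes": r.nes,
                "p_nominal": r.p_nominal,
                "fdr_q": r.fdr_q,
                "leading_edge_size": len(r.leading_edge),
                "n_perm": r.n_perm,
            }
            for r in results
        ]
    )


def wilcoxon_de(
    norm: ad.AnnData,
    group_key: str,
    positive: str | None = None,
    lnfc_cutoff: float = 0.25,
    alpha: float = 0.05,
    fc_mode: str = "shifted_mean",
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum differential expression on log-normalized data.

    ln-fold-change uses the shifted-mean convention of the major single-cell
    toolkits, ln(mean(expm1(x_pos)) + 1) - ln(mean(expm1(x_neg)) + 1), so the
    customary 0.25 natural-log cutoff applies; ``fc_mode="log_diff"`` gives
    the plain difference of log-means instead. P-values are Bonferroni
    adjusted over the tested genes and ``passes`` flags genes with
    |ln_fc| >= ``lnfc_cutoff`` and adjusted p < ``alpha``.
    """
    labels = norm.obs[group_key].astype(str).tolist()
    mask, pos, neg = _group_masks(labels, positive)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    X = np.asarray(norm.X.todense()) if hasattr(norm.X, "todense") else np.asarray(norm.X)
    A, B = X[mask], X[~mask]
    if fc_mode == "shifted_mean":
        ln_fc = np.log(np.expm1(A).mean(axis=0) + 1) - np.log(np.expm1(B).mean(axis=0) + 1)
    elif fc_mode == "log_diff":
        ln_fc = A.mean(axis=0) - B.mean(axis=0)
    else:
        raise ValueError("fc_mode must be 'shifted_mean' or 'log_diff'")
    # exact distribution for small tie-free groups, mid-rank normal
    # approximation with continuity correction otherwise
    method = "auto" if max(A.shape[0], B.shape[0]) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(A, B, alternative="two-sided", axis=0,
                             use_continuity=True, method=method)
    p = np.asarray(res.pvalue)
    m = X.shape[1]
    p_bonf = np.minimum(1.0, p * m)
    out = pd.DataFrame(
        {
            "gene": list(norm.var_names),
            "ln_fc": ln_fc,
            "p": p,
            "p_bonferroni": p_bonf,
            "passes": (np.abs(ln_fc) >= lnfc_cutoff) & (p_bonf < alpha),
        }
    )
    out.attrs["positive"] = pos
    return out


def ora(
    query,
    pathways: dict[str, list[str]],
    universe,
    fdr_alpha: float = 0.05,
) -> list[OraResult]:
    """Hypergeometric over-representation of a query list in pathway sets.

    The p-value is the upper tail P(overlap >= k) drawing |query| genes from
    a universe of size N containing K pathway genes; Benjamini-Hochberg FDR
    across pathways. Query genes outside the universe are dropped with a
    warning. Results are sorted by p.
    """
    uni = {str(g).strip().casefold() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q = {str(g).strip().casefold() for g in query}
    outside = q - uni
    if outside:
        logger.warning("%d query gene(s) outside the universe dropped", len(outside))
        q &= uni
    N, n = len(uni), len(q)
    rows = []
    for name, genes in pathways.items():
        pk = {str(g).strip().casefold() for g in genes} & uni
        K = len(pk)
        k = len(pk & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    pvals = [r[3] for r in rows]
    fdr = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")[1] if rows else []
    results = [
        OraResult(pathway=name, k_overlap=k, K_pathway=K, n_query=n,
                  N_universe=N, p=p, fdr=float(fq))
        for (name, k, K, p), fq in zip(rows, fdr)
    ]
    results.sort(key=lambda r: (r.p, r.pathway))
    return results


def ora_frame(results: list[OraResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
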