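"""Log-normalization, per-gene z-scoring and pseudobulk aggregation.

All three operations take and return the field's standard containers:
cell x gene data as :class:`anndata.AnnData`, pseudobulk as a genes x groups
:class:`pandas.DataFrame` plus a group-metadata frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)


@dataclass
class Pseudobulk:
    """Genes x groups aggregate of single-cell counts.

    ``values`` has one column per group (columns sorted by group key);
    ``group_meta`` carries the grouping key values per column.
    """

    values: pd.DataFrame
    group_meta: pd.DataFrame
    groupby: tuple[str, ...]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def lognormalize(counts: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Library-size normalize and natural-log transform.

    value(c, g) = ln(1 + counts(c, g) / total(c) * scale), the convention of
    the major single-cell toolkits. Cells with zero total counts are dropped
    with a warning, never imputed.
    """
    X = _dense(counts.X).astype(float)
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = X.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d cell(s) with zero total counts", (~keep).sum())
        X, totals = X[keep], totals[keep]
    values = np.log1p(X / totals[:, None] * scale)
    out = ad.AnnData(
        X=values,
        obs=counts.obs.loc[keep].copy(),
        var=counts.var.copy(),
    )
    out.uns["normalization"] = "lognorm"
    return out


def zscore_genes(norm: ad.AnnData, ddof: int = 1) -> ad.AnnData:
    """Standardize each gene across cells to mean 0, sd 1.

    Uses the sample standard deviation (``ddof=1``) by default; constant
    (zero-variance) genes become all-zero columns.
    """
    X = _dense(norm.X).astype(float)
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof) if X.shape[0] > ddof else np.zeros(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[:, sd == 0] = 0.0
    out = ad.AnnData(X=Z, obs=norm.obs.copy(), var=norm.var.copy())
    out.uns["normalization"] = "zscore"
    return out


def pseudobulk(
    counts: ad.AnnData,
    groupby: str | Sequence[str] = "sample_id",
    agg: str = "sum",
) -> Pseudobulk:
    """Aggregate cells into genes x groups pseudobulk profiles.

    Default aggregation is the per-group sum of raw counts; ``agg="mean"``
    averages instead (useful on log-normalized input). Column order is
    deterministic (sorted by the grouping key tuple).
    """
    keys = [groupby] if isinstance(groupby, str) else list(groupby)
    for k in keys:
        if k not in counts.obs.columns:
            raise KeyError(f"unknown cell metadata key: {k!r}")
    if agg not in ("sum", "mean"):
        raise ValueError("agg must be 'sum' or 'mean'")
    X = _dense(counts.X).astype(float)
    labels = counts.obs[keys].astype(str).agg("|".join, axis=1)
    order = sorted(labels.unique())
    cols, meta_rows = [], []
    for lab in order:
        mask = (labels == lab).to_numpy()
        block = X[mask]
        cols.append(block.sum(axis=0) if agg == "sum" else block.mean(axis=0))
        meta = dict(zip(keys, lab.split("|")))
        meta["n_cells"] = int(mask.sum())
        meta_rows.append(meta)
    values = pd.DataFrame(
        np.column_stack(cols), index=counts.var_names, columns=order
    )
    group_meta = pd.DataFrame(meta_rows, index=order)
    return Pseudobulk(values=values, group_meta=group_meta, groupby=tuple(keys))
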