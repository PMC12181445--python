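"""Synthetic skin RNA-seq data with a planted senescence program.

The generator emulates the structure of the study designs this pipeline is
aimed at: a two-condition single-cell experiment (UV-protected vs UV-exposed
skin, several cell types, multiple donors) and a two-group bulk experiment
(young vs old epidermis, 24 donors per group). Counts are negative binomial
with gene-specific means, cell-type marker boosts and lognormal library-size
factors; in the second condition a configurable fraction of cells per cell
type carries the senescence program: up-genes shifted by ``+effect_delta``
and down-genes by ``-down_delta`` on the natural-log mean scale, so effect
sizes are directly comparable to ln-fold-change cutoffs used downstream.
Ground-truth flags (``truth_affected``) are recorded per cell so tests can
score recovery without re-deriving the truth.

This module is a statistical stand-in for real accessions: it reproduces
overdispersion, sparsity, cell-type structure and a signed expression program,
not batch effects, doublets or ambient RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .geneset import SignedGeneSet

DEFAULT_CELL_TYPES: tuple[tuple[str, int], ...] = (
    ("fibroblast", 200),
    ("keratinocyte", 200),
    ("T_cell", 200),
    ("pericyte", 200),
    ("vascular_EC", 200),
    ("macrophage", 200),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    ``cell_types`` lists ``(name, n_cells_per_condition)`` pairs (single-cell
    mode only). ``effect_delta`` / ``down_delta`` are natural-log mean shifts
    applied to the up-/down-genes of the embedded signed set in affected
    cells (or in every condition-2 sample in bulk mode, where the shift is
    the tissue-average effect). ``nb_dispersion`` is the negative-binomial
    dispersion alpha in var = mu + alpha*mu^2; ``libsize_lognormal`` gives
    (mu, sigma) of the per-cell/per-sample lognormal size factor.
    """

    n_genes: int = 2000
    cell_types: tuple[tuple[str, int], ...] = DEFAULT_CELL_TYPES
    conditions: tuple[str, str] = ("UVprotected", "UVexposed")
    n_samples_per_condition: int = 5
    effect_delta: float = 1.0
    affected_fraction: float | dict[str, float] = 0.3
    down_delta: float = 1.0
    nb_dispersion: float = 0.5
    libsize_lognormal: tuple[float, float] = (0.0, 0.3)
    base_logmean: tuple[float, float] = (-2.0, 1.0)
    marker_fraction: float = 0.05
    marker_boost: float = np.log(4.0)
    bulk_depth: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = tuple((str(n), int(c)) for n, c in self.cell_types)
        self.conditions = tuple(self.conditions)
        self.libsize_lognormal = tuple(float(v) for v in self.libsize_lognormal)
        self.base_logmean = tuple(float(v) for v in self.base_logmean)
        for name in ("effect_delta", "down_delta", "nb_dispersion",
                     "marker_fraction", "marker_boost", "bulk_depth"):
            setattr(self, name, float(getattr(self, name)))
        if len(self.conditions) != 2:
            raise ValueError("conditions must have exactly 2 labels")
        fracs = (self.affected_fraction.values()
                 if isinstance(self.affected_fraction, dict)
                 else [self.affected_fraction])
        if not all(0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("affected_fraction must be in [0, 1]")
        if self.n_genes <= 0 or self.n_samples_per_condition <= 0:
            raise ValueError("n_genes and n_samples_per_condition must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.effect_delta < 0 or self.down_delta < 0:
            raise ValueError("effect deltas must be nonnegative")
        if any(c <= 0 for _, c in self.cell_types):
            raise ValueError("cell counts must be positive")

    @classmethod
    def default_bulk(cls, **overrides) -> "SimulationConfig":
        """Defaults mirroring a 24-vs-24-donor bulk design."""
        overrides.setdefault("n_samples_per_condition", 24)
        overrides.setdefault("conditions", ("young", "old"))
        overrides.setdefault("nb_dispersion", 0.1)
        return cls(**overrides)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _gene_universe(config: SimulationConfig, signed_set: SignedGeneSet) -> list[str]:
    names = [f"BG{i + 1:04d}" for i in range(config.n_genes)]
    have = {g.casefold() for g in names}
    for g in signed_set.all_genes:
        if g.casefold() not in have:
            names.append(g)
    return names


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    # Gamma-Poisson mixture: var = mu + alpha*mu^2
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def simulate_sc(config: SimulationConfig, signed_set: SignedGeneSet) -> ad.AnnData:
    """Simulate a cell x gene count matrix with a planted senescence program.

    Returns an :class:`anndata.AnnData` with raw integer counts in ``.X``
    (sparse CSR) and per-cell ``cell_type``, ``condition``, ``sample_id`` and
    ``truth_affected`` in ``.obs``. Deterministic for a fixed config (the
    seed lives in the config).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config, signed_set)
    gene_index = {g.casefold(): j for j, g in enumerate(genes)}
    up_idx = np.array([gene_index[g.casefold()] for g in signed_set.up_genes])
    dn_idx = np.array([gene_index[g.casefold()] for g in signed_set.down_genes])
    n_genes = len(genes)

    mu0, sd0 = config.base_logmean
    base = rng.normal(mu0, sd0, size=n_genes)

    # cell-type-specific marker boosts
    type_logmean = {}
    n_markers = max(1, int(round(config.marker_fraction * n_genes)))
    for name, _ in config.cell_types:
        boost = np.zeros(n_genes)
        marker_idx = rng.choice(n_genes, size=n_markers, replace=False)
        boost[marker_idx] = config.marker_boost
        type_logmean[name] = base + boost

    frac_of = (
        (lambda ct: config.affected_fraction.get(ct, 0.0))
        if isinstance(config.affected_fraction, dict)
        else (lambda ct: config.affected_fraction)
    )
    rows_ct, rows_cond, rows_sample, rows_aff = [], [], [], []
    blocks = []
    for name, n_cells in config.cell_types:
        for cond_i, cond in enumerate(config.conditions):
            logmean = np.tile(type_logmean[name], (n_cells, 1))
            affected = np.zeros(n_cells, dtype=bool)
            if cond_i == 1 and frac_of(name) > 0:
                affected = rng.random(n_cells) < frac_of(name)
                if affected.any():
                    if up_idx.size:
                        logmean[np.ix_(affected, up_idx)] += config.effect_delta
                    if dn_idx.size:
                        logmean[np.ix_(affected, dn_idx)] -= config.down_delta
            size = rng.lognormal(*config.libsize_lognormal, size=n_cells)
            mean = np.exp(logmean) * size[:, None]
            counts = _nb_counts(rng, mean, config.nb_dispersion)
            blocks.append(sp.csr_matrix(counts))
            donors = rng.integers(config.n_samples_per_condition, size=n_cells)
            rows_ct.extend([name] * n_cells)
            rows_cond.extend([cond] * n_cells)
            rows_sample.extend([f"{cond}_donor{d + 1}" for d in donors])
            rows_aff.extend(affected.tolist())

    X = sp.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical(rows_ct),
            "condition": pd.Categorical(rows_cond, categories=list(config.conditions)),
            "sample_id": rows_sample,
            "truth_affected": np.array(rows_aff, dtype=bool),
        },
        index=[f"cell{i + 1}" for i in range(X.shape[0])],
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    adata.uns["simulation"] = asdict(config)
    return adata


def simulate_bulk(
    config: SimulationConfig, signed_set: SignedGeneSet
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a genes x samples bulk count table with a group-2 signed shift.

    Every condition-2 sample carries the full up/down shift (the tissue-level
    average of the program). Returns the count DataFrame (genes as rows,
    samples as columns) and the per-sample group labels.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config, signed_set)
    gene_index = {g.casefold(): j for j, g in enumerate(genes)}
    up_idx = np.array([gene_index[g.casefold()] for g in signed_set.up_genes])
    dn_idx = np.array([gene_index[g.casefold()] for g in signed_set.down_genes])
    n_genes = len(genes)
    n = config.n_samples_per_condition

    mu0, sd0 = config.base_logmean
    base = rng.normal(mu0, sd0, size=n_genes)

    cols, groups, names = [], [], []
    for cond_i, cond in enumerate(config.conditions):
        logmean = base.copy()
        if cond_i == 1:
            if up_idx.size:
                logmean[up_idx] += config.effect_delta
            if dn_idx.size:
                logmean[dn_idx] -= config.down_delta
        size = rng.lognormal(*config.libsize_lognormal, size=n)
        mean = np.exp(logmean)[:, None] * size[None, :] * config.bulk_depth
        cols.append(_nb_counts(rng, mean, config.nb_dispersion))
        groups.extend([cond] * n)
        names.extend([f"{cond}_s{i + 1}" for i in range(n)])

    mat = pd.DataFrame(np.hstack(cols), index=genes, columns=names)
    return mat, groups


def write_sc_mtx(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write counts as MTX plus gene-name and cell-metadata TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "counts.mtx"), sp.coo_matrix(adata.X))
    pd.Series(adata.var_names, name="gene").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    return outdir


def read_sc_mtx(indir: str | Path) -> ad.AnnData:
    """Read a cell x gene matrix written by :func:`write_sc_mtx`."""
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "counts.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].astype(str).tolist()
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
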