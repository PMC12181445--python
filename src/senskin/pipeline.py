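"""End-to-end orchestration: simulate/load -> normalize -> score -> contrast
-> cluster -> GSEA/ORA, from one YAML config, with a reproducibility manifest.

All randomness flows from one master seed expanded deterministically into
per-stage seeds; the manifest records the config, the expanded seeds, the
package version and a checksum of every output file, so identical
config+seed reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .geneset import SignedGeneSet, builtin_senskin, read_signed_gmt
from .synthetic_data import SimulationConfig, simulate_sc, simulate_bulk
from .preprocess import lognormalize, zscore_genes, pseudobulk
from .scoring import composite_score, contrast_by_celltype, contrasts_frame
from .correlation_clustering import gated_log_transform, gene_correlation, complete_linkage
from .enrichment import gsea_phenotype, gsea_frame, ora, ora_frame

_STAGES = ("score", "contrast", "cluster", "gsea", "ora")


@dataclass
class PipelineConfig:
    """Flat per-stage configuration; every field mirrors a module knob."""

    seed: int = 0
    gene_set: str = "builtin:senskin"
    input_dir: str | None = None  # MTX+TSV directory; None -> simulate
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: s != "ora" for s in _STAGES}
    )
    simulate: dict[str, Any] = field(default_factory=dict)
    bulk: dict[str, Any] = field(default_factory=dict)
    preprocess: dict[str, Any] = field(default_factory=lambda: {"scale": 1e4})
    contrast: dict[str, Any] = field(
        default_factory=lambda: {"alpha": 0.05, "adjust": "bonferroni"}
    )
    cluster: dict[str, Any] = field(
        default_factory=lambda: {
            "k": 5,
            "skew_threshold": 2.0,
            "log_mode": "global",
            "groupby": ["sample_id"],
        }
    )
    gsea: dict[str, Any] = field(default_factory=lambda: {"n_perm": 1000})
    ora: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the input."""


def _load_gene_set(spec: str) -> SignedGeneSet:
    if spec == "builtin:senskin":
        return builtin_senskin()
    path = Path(spec)
    if not path.exists():
        raise StageError(f"gene_set: file not found: {spec!r}")
    sets = read_signed_gmt(path)
    if not sets:
        raise StageError(f"gene_set: no sets in {spec!r}")
    return sets[0]


def _stage_seeds(master: int) -> dict[str, int]:
    state = np.random.SeedSequence(int(master)).generate_state(6)
    names = ("simulate_sc", "simulate_bulk", "gsea", "spare1", "spare2", "spare3")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute enabled stages in dependency order; return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    gene_set = _load_gene_set(config.gene_set)
    outputs: dict[str, Path] = {}
    enabled = {**{s: s != "ora" for s in _STAGES}, **(config.stages or {})}

    try:
        if config.input_dir is not None:
            from .synthetic_data import read_sc_mtx

            adata = read_sc_mtx(config.input_dir)
        else:
            sim = SimulationConfig(**{**config.simulate, "seed": seeds["simulate_sc"]})
            adata = simulate_sc(sim, gene_set)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"input: {exc}") from exc

    try:
        norm = lognormalize(adata, scale=float(config.preprocess.get("scale", 1e4)))
        z = zscore_genes(norm)
    except Exception as exc:
        raise StageError(f"preprocess: {exc}") from exc

    if enabled.get("score", True):
        try:
            table = composite_score(z, gene_set)
            path = outdir / "scores.tsv"
            table.scores.to_csv(path, sep="\t")
            outputs["scores"] = path
        except Exception as exc:
            raise StageError(f"score: {exc}") from exc

        if enabled.get("contrast", True):
            try:
                res = contrast_by_celltype(table, **config.contrast)
                path = outdir / "contrasts.tsv"
                contrasts_frame(res).to_csv(path, sep="\t", index=False)
                outputs["contrasts"] = path
            except Exception as exc:
                raise StageError(f"contrast: {exc}") from exc

    if enabled.get("cluster", True):
        try:
            cl_cfg = config.cluster
            pb = pseudobulk(adata, groupby=cl_cfg.get("groupby", ["sample_id"]))
            present = [g for g in gene_set.all_genes if g in pb.values.index]
            pb.values = pb.values.loc[present]
            pb_t, triggered = gated_log_transform(
                pb,
                threshold=float(cl_cfg.get("skew_threshold", 2.0)),
                mode=cl_cfg.get("log_mode", "global"),
            )
            corr = gene_correlation(pb_t)
            clustering = complete_linkage(corr, k=int(cl_cfg.get("k", 5)))
            corr.to_csv(outdir / "gene_correlation.tsv", sep="\t")
            clustering.assignment.to_frame().assign(
                dendrogram_position=[
                    clustering.dendrogram_order.index(g) for g in clustering.genes
                ]
            ).to_csv(outdir / "gene_clusters.tsv", sep="\t")
            outputs["gene_correlation"] = outdir / "gene_correlation.tsv"
            outputs["gene_clusters"] = outdir / "gene_clusters.tsv"
        except Exception as exc:
            raise StageError(f"cluster: {exc}") from exc

    if enabled.get("gsea", True):
        try:
            bulk_cfg = SimulationConfig.default_bulk(
                **{**config.bulk, "seed": seeds["simulate_bulk"]}
            )
            expr, groups = simulate_bulk(bulk_cfg, gene_set)
            results = gsea_phenotype(
                expr,
                groups,
                [gene_set],
                n_perm=int(config.gsea.get("n_perm", 1000)),
                seed=seeds["gsea"],
            )
            path = outdir / "gsea.tsv"
            gsea_frame(results).to_csv(path, sep="\t", index=False)
            outputs["gsea"] = path
        except Exception as exc:
            raise StageError(f"gsea: {exc}") from exc

    if enabled.get("ora", False):
        try:
            gmt = config.ora.get("pathways_gmt")
            if not gmt:
                raise ValueError("ora.pathways_gmt is required when the ora stage is on")
            pathway_sets = {s.name: list(s.all_genes) for s in read_signed_gmt(gmt)}
            results = ora(
                list(gene_set.all_genes), pathway_sets, list(adata.var_names),
                fdr_alpha=float(config.ora.get("fdr_alpha", 0.05)),
            )
            path = outdir / "ora.tsv"
            ora_frame(results).to_csv(path, sep="\t", index=False)
            outputs["ora"] = path
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"ora: {exc}") from exc

    config_blob = json.dumps(config.__dict__, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "gene_set": gene_set.name,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
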