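"""End-to-end orchestration: linkage -> ReL matrix -> modules -> annotation.

A run is described by a RunConfig (paths plus every tunable); the resolved
configuration is serialized into the output directory for provenance, stage
outputs are written as they complete, and a failure aborts with the stage
name while retaining partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as _annotate
from . import biclust, io, linkage, relscore

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotypes: str
    marker_map: str
    expression: str
    compendium: str
    compendium_meta: str
    out_dir: str
    gene_positions: str | None = None
    annotation: str | None = None
    network: str | None = None
    binding_targets: str | None = None
    chrom_lengths: str | None = None
    min_shared_segregants: int = linkage.MIN_SHARED_SEGREGANTS
    min_shared_genes: int = relscore.MIN_SHARED_GENES
    tau_row: float = 3.0
    tau_col: float = 3.0
    max_iter: int = 50
    min_markers: int = 1
    min_signatures: int = 1
    score_floor: float = 3.0
    min_seed_score: float | None = 3.0   # None = seed from every entry
    jaccard_cutoff: float = 0.5
    target_frac: float = _annotate.TARGET_FRAC
    cis_gene_window: int = _annotate.CIS_GENE_WINDOW
    enrich_alpha: float = 0.05
    enrich_correction: str = "bonferroni"
    n_perm: int = 0                      # permutation P-values when > 0
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(out / "run_config.yaml")
    counts: dict[str, object] = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("read inputs")
        genotypes = io.read_genotypes(config.genotypes)
        mmap = io.read_marker_map(config.marker_map)
        expression = io.read_expression(config.expression)
        compendium = io.read_compendium(config.compendium, config.compendium_meta)
        gene_positions = (
            io.read_gene_positions(config.gene_positions) if config.gene_positions else None
        )
        annotation = None
        if config.annotation:
            # enrichment universe: expression genes that carry any annotation record
            annotation = io.read_annotation(config.annotation).restrict(expression.gene_ids)
        network = io.read_network(config.network) if config.network else None
        binding = (
            io.read_binding_targets(config.binding_targets) if config.binding_targets else None
        )
        chrom_lengths = (
            io.read_chrom_lengths(config.chrom_lengths) if config.chrom_lengths else None
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("read inputs", exc) from exc

    try:
        stage("linkage")
        lmat = linkage.compute_linkage_matrix(
            genotypes, expression, config.min_shared_segregants
        )
        counts["n_markers"] = len(lmat.marker_ids)
        counts["n_genes_linkage"] = len(lmat.gene_ids)
    except Exception as exc:  # noqa: BLE001
        raise StageError("linkage", exc) from exc

    try:
        stage("relscore")
        rel = relscore.compute_rel_matrix(lmat, compendium, mmap, config.min_shared_genes)
        rel.save(out / "rel_matrix")
        counts["n_rel_entries"] = rel.n_entries
        counts["bonferroni_factor"] = rel.n_tests
        counts["n_entries_significant"] = int((rel.rel_score > 0).sum())
    except Exception as exc:  # noqa: BLE001
        raise StageError("relscore", exc) from exc

    try:
        stage("modules")
        params = biclust.ISAParams(
            tau_row=config.tau_row,
            tau_col=config.tau_col,
            max_iter=config.max_iter,
            min_signatures=config.min_signatures,
            min_markers=config.min_markers,
            score_floor=config.score_floor,
        )
        modules = biclust.find_modules(
            rel, params, config.min_seed_score, config.jaccard_cutoff
        )
        counts["n_seeds"] = len(
            biclust.seed_entries(rel, config.min_seed_score or 0.0)
        )
        counts["n_modules"] = len(modules)
        perm_p = []
        if config.n_perm > 0:
            for m in modules:
                perm_p.append(
                    biclust.module_size_pvalue(m, rel, config.n_perm, config.rng_seed, params)
                )
        counts["module_size_pvalues"] = perm_p
    except Exception as exc:  # noqa: BLE001
        raise StageError("modules", exc) from exc

    try:
        stage("annotate")
        annotated = [
            _annotate.annotate_module(
                m, rel, compendium.protein_of,
                gene_positions=gene_positions,
                annotation=annotation,
                network=network,
                binding_targets=binding,
                chrom_lengths=chrom_lengths,
                frac=config.target_frac,
                cis_gene_window=config.cis_gene_window,
                alpha=config.enrich_alpha,
                correction=config.enrich_correction,
            )
            for m in modules
        ]
        io.write_module_report(annotated, out / "modules.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", exc) from exc

    with open(out / "run_counts.json", "w", encoding="utf-8") as fh:
        json.dump(counts, fh, indent=1)
    logger.info("pipeline complete: %s", counts)
    return out
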