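"""Module annotation: target genes, protein scores, enrichment, causal regulators.

Target genes are the hit genes shared by at least ``frac`` (default 60%) of a
module's interval x signature entries, minus cis genes — genes inside the
linkage interval or fewer than ``cis_gene_window`` (default 30) genes away
from it in chromosome gene order.  Each regulatory protein is scored by the
mean ReL score of its signatures over the interval; target genes are tested
for functional-term enrichment (hypergeometric, multiplicity-corrected), and
interval genes are ranked as putative causal regulators by three criteria:
annotation with the primary process, a direct network link to a module
protein, or enrichment of the gene's binding targets among the module's
target genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .biclust import ReLModule
from .io import AnnotationSet
from .relscore import ReLMatrix

logger = logging.getLogger(__name__)

TARGET_FRAC = 0.6
CIS_GENE_WINDOW = 30


@dataclass
class AnnotatedModule:
    base: ReLModule
    target_genes: frozenset[str]
    protein_scores: dict[str, float]
    primary_process: str | None
    enrichments: list[tuple[str, float]]
    causal_candidates: list[tuple[str, frozenset[str]]]
    telomere_flag: bool = False


def _chrom_gene_order(gene_positions: pd.DataFrame, chrom: str):
    sub = gene_positions[gene_positions["chromosome"] == chrom]
    sub = sub.sort_values(["position_kb"], kind="stable")
    return list(sub.index), sub["position_kb"].to_numpy(dtype=float)


def cis_gene_set(
    gene_positions: pd.DataFrame,
    chrom: str,
    start_kb: float,
    end_kb: float,
    cis_gene_window: int = CIS_GENE_WINDOW,
) -> frozenset[str]:
    """Genes inside [start_kb, end_kb] on ``chrom`` or fewer than
    ``cis_gene_window`` genes away from it in gene order (the nearest outside
    gene counts as 1 away)."""
    order, pos = _chrom_gene_order(gene_positions, chrom)
    if not order:
        return frozenset()
    lo = int(np.searchsorted(pos, start_kb, side="left"))
    hi = int(np.searchsorted(pos, end_kb, side="right")) - 1
    cis = set()
    for j, g in enumerate(order):
        if lo <= j <= hi:
            cis.add(g)  # inside the interval
        else:
            dist = (lo - j) if j < lo else (j - hi)
            if dist < cis_gene_window:
                cis.add(g)
    return frozenset(cis)


def target_genes(
    module: ReLModule,
    rel_matrix_hit_sets: dict,
    gene_positions: pd.DataFrame | None,
    frac: float = TARGET_FRAC,
    cis_gene_window: int = CIS_GENE_WINDOW,
) -> frozenset[str]:
    """Hit genes present in >= frac of the module's entries, cis genes excluded.

    ``rel_matrix_hit_sets`` maps (marker_id, signature_id) to a hit gene set
    (see ReLMatrix.hit_gene_sets()).  Genes without a position cannot be
    cis-excluded and are retained with a warning.
    """
    entries = [(m, s) for m in module.marker_ids for s in module.signatures]
    counts: dict[str, int] = {}
    for key in entries:
        for g in rel_matrix_hit_sets.get(key, ()):
            counts[g] = counts.get(g, 0) + 1
    need = frac * len(entries) - 1e-9
    recurrent = {g for g, c in counts.items() if c >= need}
    if gene_positions is None:
        logger.warning("no gene positions: cis exclusion skipped")
        return frozenset(recurrent)
    unpositioned = recurrent - set(gene_positions.index)
    if unpositioned:
        logger.warning(
            "%d hit genes lack positions and cannot be cis-excluded: %s",
            len(unpositioned), sorted(unpositioned)[:5],
        )
    cis = cis_gene_set(
        gene_positions, module.chromosome, module.start_kb, module.end_kb, cis_gene_window
    )
    return frozenset(recurrent - cis)


def protein_scores(module: ReLModule, rel: ReLMatrix, protein_of: dict[str, str]) -> dict[str, float]:
    """Mean interval ReL score per regulatory protein of the module.

    A protein mutated in several of the module's signatures gets the mean of
    its per-signature interval means.
    """
    lo, hi = module.start, module.end
    per_sig = {
        s: float(rel.rel_score[lo : hi + 1, j].mean())
        for s, j in zip(module.signatures, module.signature_idx)
    }
    by_protein: dict[str, list[float]] = {}
    for s, v in per_sig.items():
        by_protein.setdefault(protein_of[s], []).append(v)
    return {p: float(np.mean(v)) for p, v in by_protein.items()}


def enrich(
    targets,
    annotation: AnnotationSet,
    alpha: float = 0.05,
    method: str = "bonferroni",
):
    """Hypergeometric term enrichment of a target gene set.

    The universe is the annotation's (already restricted) universe; P-values
    are corrected over all tested terms (``method``: "bonferroni" or "fdr_bh").
    Returns (enrichments, primary_process): significant (term, corrected P)
    pairs sorted by corrected P then term id, and the best term (or None).
    """
    targets = frozenset(targets) & annotation.universe
    if not targets:
        return [], None
    N = len(annotation.universe)
    n = len(targets)
    tested = [(t, genes) for t, genes in sorted(annotation.terms.items()) if genes]
    if not tested:
        return [], None
    pvals = np.array(
        [stats.hypergeom.sf(len(targets & genes) - 1, N, len(genes), n) for _, genes in tested]
    )
    _, p_corr, _, _ = multipletests(pvals, alpha=alpha, method=method)
    hits = [
        (t, float(p)) for (t, _), p in zip(tested, p_corr) if p < alpha
    ]
    hits.sort(key=lambda x: (x[1], x[0]))
    primary = hits[0][0] if hits else None
    return hits, primary


def interval_genes(gene_positions: pd.DataFrame, chrom, start_kb, end_kb) -> list[str]:
    sub = gene_positions[
        (gene_positions["chromosome"] == chrom)
        & (gene_positions["position_kb"] >= start_kb)
        & (gene_positions["position_kb"] <= end_kb)
    ]
    return sorted(sub.index)


def causal_candidates(
    module: ReLModule,
    gene_positions: pd.DataFrame,
    annotation: AnnotationSet | None,
    network: nx.Graph | None,
    binding_targets: dict[str, frozenset[str]] | None,
    module_targets,
    primary_process: str | None,
    module_proteins,
    alpha: float = 0.05,
) -> list[tuple[str, frozenset[str]]]:
    """Rank interval genes as putative causal regulators.

    Criteria: (process) the gene is annotated with the module's primary
    biological process; (interaction) the interaction network links it
    directly to one of the module's regulatory proteins; (binding) its known
    binding targets are enriched (corrected hypergeometric P < alpha) among
    the module's target genes.  Genes meeting >= 1 criterion are returned
    ranked by criteria count, then binding P, then id.
    """
    genes = interval_genes(gene_positions, module.chromosome, module.start_kb, module.end_kb)
    module_targets = frozenset(module_targets)
    proteins = set(module_proteins)

    binding_p: dict[str, float] = {}
    if binding_targets and annotation is not None and module_targets:
        universe = annotation.universe
        n = len(module_targets & universe)
        tested = [g for g in genes if g in binding_targets]
        raw = []
        for g in tested:
            tg = binding_targets[g] & universe
            k = len(tg & module_targets)
            raw.append(stats.hypergeom.sf(k - 1, len(universe), len(tg), n))
        if tested:
            _, p_corr, _, _ = multipletests(np.array(raw), alpha=alpha, method="bonferroni")
            binding_p = dict(zip(tested, (float(p) for p in p_corr)))

    out = []
    for g in genes:
        flags = set()
        if primary_process is not None and annotation is not None:
            if g in annotation.terms.get(primary_process, frozenset()):
                flags.add("process")
        if network is not None and g in network:
            if any(p in network[g] for p in proteins):
                flags.add("interaction")
        if binding_p.get(g, 1.0) < alpha:
            flags.add("binding")
        if flags:
            out.append((g, frozenset(flags)))
    out.sort(key=lambda x: (-len(x[1]), binding_p.get(x[0], 1.0), x[0]))
    return out


def telomere_flag(
    targets,
    gene_positions: pd.DataFrame,
    chrom_lengths: dict[str, float],
    telomere_kb: float = 30.0,
    min_frac: float = 0.5,
    min_chroms: int = 3,
) -> bool:
    """True when the target set is dominated by (sub)telomeric genes spread
    over several chromosomes: >= min_frac of positioned targets lie within
    telomere_kb (inclusive) of a chromosome end, on >= min_chroms chromosomes."""
    positioned = [g for g in targets if g in gene_positions.index]
    if len(positioned) < len(list(targets)):
        logger.warning("telomere flag: %d unpositioned target genes ignored",
                       len(list(targets)) - len(positioned))
    if not positioned:
        return False
    telo_chroms = set()
    n_telo = 0
    for g in positioned:
        chrom = gene_positions.at[g, "chromosome"]
        if chrom not in chrom_lengths:
            continue
        pos = float(gene_positions.at[g, "position_kb"])
        if pos <= telomere_kb or (chrom_lengths[chrom] - pos) <= telomere_kb:
            n_telo += 1
            telo_chroms.add(chrom)
    return (n_telo / len(positioned)) >= min_frac and len(telo_chroms) >= min_chroms


def annotate_module(
    module: ReLModule,
    rel: ReLMatrix,
    protein_of: dict[str, str],
    gene_positions: pd.DataFrame | None = None,
    annotation: AnnotationSet | None = None,
    network: nx.Graph | None = None,
    binding_targets: dict[str, frozenset[str]] | None = None,
    chrom_lengths: dict[str, float] | None = None,
    frac: float = TARGET_FRAC,
    cis_gene_window: int = CIS_GENE_WINDOW,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> AnnotatedModule:
    """Derive every annotation layer for one module (tables may be omitted)."""
    hits = rel.hit_gene_sets()
    targets = target_genes(module, hits, gene_positions, frac, cis_gene_window)
    pscores = protein_scores(module, rel, protein_of)
    enrichments: list[tuple[str, float]] = []
    primary = None
    if annotation is not None:
        enrichments, primary = enrich(targets, annotation, alpha, correction)
    candidates: list[tuple[str, frozenset[str]]] = []
    if gene_positions is not None:
        candidates = causal_candidates(
            module, gene_positions, annotation, network, binding_targets,
            targets, primary, set(pscores), alpha,
        )
    flag = False
    if gene_positions is not None and chrom_lengths:
        flag = telomere_flag(targets, gene_positions, chrom_lengths)
    return AnnotatedModule(
        base=module,
        target_genes=targets,
        protein_scores=pscores,
        primary_process=primary,
        enrichments=enrichments,
        causal_candidates=candidates,
        telomere_flag=flag,
    )
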