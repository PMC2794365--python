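"""Readers, writers and validated containers for every external representation.

All tabular formats are UTF-8, tab-delimited with a header row, except the
marker map which is BED-like (no header: chromosome, position_kb, marker_id).
Readers never reorder rows or columns; joins between containers are performed
by the consumers, by id intersection, with a logged count of dropped ids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False, **kw
    )


def _check_unique(ids: Sequence[str], what: str, path) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dup = s[s.duplicated()][0]
        raise FormatError(f"{path}: duplicate {what} id {dup!r}")


@dataclass
class GenotypeMatrix:
    """Biallelic marker calls for a haploid segregating population.

    ``calls`` is markers x segregants with values 0 (parent A allele),
    1 (parent B allele) or NaN (missing).
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.calls.to_numpy(dtype=float)
        bad = ~(np.isnan(v) | (v == 0.0) | (v == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary genotype call {v[i, j]!r} at marker "
                f"{self.calls.index[i]!r}, segregant {self.calls.columns[j]!r}"
            )
        _check_unique(self.calls.index, "marker", "<genotypes>")
        _check_unique(self.calls.columns, "segregant", "<genotypes>")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def segregant_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class ExpressionMatrix:
    """Log-ratio expression, genes x samples; NaN marks missing values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.isinf(v).any():
            i, j = np.argwhere(np.isinf(v))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        _check_unique(self.values.index, "gene", "<expression>")
        _check_unique(self.values.columns, "sample", "<expression>")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MarkerMap:
    """Genomic location of each marker: chromosome label and position in kb.

    Chromosome order is the order of first appearance in the file; within a
    chromosome markers sort by position (ties by marker id).
    """

    table: pd.DataFrame  # index marker_id; columns: chromosome, position_kb

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "marker", "<marker map>")
        pos = self.table["position_kb"].to_numpy(dtype=float)
        if (pos < 0).any() or np.isnan(pos).any():
            bad = self.table.index[(pos < 0) | np.isnan(pos)][0]
            raise FormatError(f"negative or missing position for marker {bad!r}")

    @property
    def chromosome_order(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def genomic_order(self, marker_ids: Iterable[str]) -> list[str]:
        """Sort the given markers genomically; every id must be mapped."""
        ids = list(marker_ids)
        missing = [m for m in ids if m not in self.table.index]
        if missing:
            raise KeyError(f"markers absent from marker map: {missing[:5]}")
        sub = self.table.loc[ids]
        chrom_rank = {c: i for i, c in enumerate(self.chromosome_order)}
        order = sorted(
            ids,
            key=lambda m: (
                chrom_rank[sub.at[m, "chromosome"]],
                sub.at[m, "position_kb"],
                m,
            ),
        )
        return order

    def chromosome(self, marker_id: str) -> str:
        return self.table.at[marker_id, "chromosome"]

    def position_kb(self, marker_id: str) -> float:
        return float(self.table.at[marker_id, "position_kb"])


@dataclass
class SignatureCompendium:
    """Expression profiles of single-gene regulatory mutants.

    ``values`` is genes x signatures (log2 mutant/wild-type); ``protein_of``
    maps every signature id to the mutated regulatory protein.  Several
    signatures may map to the same protein (repeated mutants), but each
    signature maps to exactly one protein.
    """

    values: pd.DataFrame
    protein_of: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene", "<compendium>")
        _check_unique(self.values.columns, "signature", "<compendium>")
        missing = [s for s in self.values.columns if s not in self.protein_of]
        if missing:
            raise FormatError(f"signatures without protein metadata: {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def signature_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AnnotationSet:
    """Flattened functional annotation: term id -> gene set, plus a universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, genes in self.terms.items():
            if not genes <= self.universe:
                raise FormatError(f"term {t!r} annotates genes outside the universe")

    def restrict(self, genes: Iterable[str]) -> "AnnotationSet":
        """Intersect the universe (and every term) with ``genes``."""
        uni = self.universe & frozenset(genes)
        return AnnotationSet(
            terms={t: g & uni for t, g in self.terms.items()},
            universe=uni,
            names=dict(self.names),
        )


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path) -> GenotypeMatrix:
    df = _read_tsv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    _check_unique(df.index, "marker", path)
    _check_unique(df.columns, "segregant", path)
    try:
        num = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric genotype call ({exc})") from exc
    v = num.to_numpy(dtype=float)
    bad = ~(np.isnan(v) | (v == 0.0) | (v == 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: genotype call {df.iat[i, j]!r} is not 0/1/{MISSING_TOKEN} "
            f"(marker {df.index[i]!r}, segregant {df.columns[j]!r})"
        )
    return GenotypeMatrix(calls=num.astype(float))


def read_expression(path) -> ExpressionMatrix:
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float))


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "position_kb", "marker_id"],
        dtype={"chromosome": str, "marker_id": str},
    )
    _check_unique(df["marker_id"], "marker", path)
    table = df.set_index("marker_id")[["chromosome", "position_kb"]]
    table["position_kb"] = pd.to_numeric(table["position_kb"])
    return MarkerMap(table=table)


def write_marker_map(mmap: MarkerMap, path) -> None:
    out = mmap.table.reset_index()[["chromosome", "position_kb", "index"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_compendium(matrix_path, meta_path) -> SignatureCompendium:
    values = _read_tsv(matrix_path, index_col=0).astype(float)
    values.index = values.index.astype(str)
    meta = _read_tsv(meta_path, dtype=str)
    if list(meta.columns[:2]) != ["signature_id", "protein"]:
        raise FormatError(
            f"{meta_path}: expected columns signature_id, protein; got {list(meta.columns)}"
        )
    if meta["signature_id"].duplicated().any():
        dup = meta["signature_id"][meta["signature_id"].duplicated()].iloc[0]
        raise FormatError(f"{meta_path}: signature {dup!r} listed twice")
    protein_of = dict(zip(meta["signature_id"], meta["protein"]))
    return SignatureCompendium(values=values, protein_of=protein_of)


def write_compendium(comp: SignatureCompendium, matrix_path, meta_path) -> None:
    comp.values.to_csv(matrix_path, sep="\t", na_rep=MISSING_TOKEN)
    meta = pd.DataFrame(
        {"signature_id": comp.signature_ids,
         "protein": [comp.protein_of[s] for s in comp.signature_ids]}
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_annotation(path, universe: Iterable[str] | None = None) -> AnnotationSet:
    """Two-column table gene_id<TAB>term_id (header row); optional term names
    in a third column."""
    df = _read_tsv(path, dtype=str)
    if "gene_id" not in df.columns or "term_id" not in df.columns:
        raise FormatError(f"{path}: expected columns gene_id, term_id")
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        terms.setdefault(row.term_id, set()).add(row.gene_id)
        if hasattr(row, "term_name") and isinstance(row.term_name, str):
            names[row.term_id] = row.term_name
    uni = frozenset(df["gene_id"]) if universe is None else frozenset(universe)
    return AnnotationSet(
        terms={t: frozenset(g & uni) for t, g in terms.items()},
        universe=uni,
        names=names,
    )


def read_network(path) -> nx.Graph:
    """Edge list node_a<TAB>node_b<TAB>kind (kind in {protein-protein,
    protein-DNA}); returns an undirected graph with a ``kind`` edge attribute."""
    df = _read_tsv(path, dtype=str)
    need = {"node_a", "node_b", "kind"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, kind=row.kind)
    return g


def read_binding_targets(path) -> dict[str, frozenset[str]]:
    """regulator<TAB>target table -> map regulator -> target gene set."""
    df = _read_tsv(path, dtype=str)
    if not {"regulator", "target"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns regulator, target")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.regulator, set()).add(row.target)
    return {k: frozenset(v) for k, v in out.items()}


def read_gene_positions(path) -> pd.DataFrame:
    """gene_id<TAB>chromosome<TAB>position_kb -> DataFrame indexed by gene."""
    df = _read_tsv(path, dtype={"gene_id": str, "chromosome": str})
    need = {"gene_id", "chromosome", "position_kb"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    _check_unique(df["gene_id"], "gene", path)
    out = df.set_index("gene_id")[["chromosome", "position_kb"]]
    out["position_kb"] = pd.to_numeric(out["position_kb"])
    return out


def read_chrom_lengths(path) -> dict[str, float]:
    df = _read_tsv(path, dtype={"chromosome": str})
    if not {"chromosome", "length_kb"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns chromosome, length_kb")
    return dict(zip(df["chromosome"], pd.to_numeric(df["length_kb"])))


# ---------------------------------------------------------------------------
# module report


def format_interval(chrom: str, start_kb: float, end_kb: float) -> str:
    """Render an inclusive marker interval as e.g. ``II:352–376``."""

    def fmt(x: float) -> str:
        return f"{int(x)}" if float(x).is_integer() else f"{x:g}"

    return f"{chrom}:{fmt(start_kb)}–{fmt(end_kb)}"


def write_module_report(modules: Sequence, path) -> None:
    """Write the per-module summary TSV plus a JSON sidecar with full member
    lists.  ``modules`` are AnnotatedModule objects (see relmod.annotate);
    an empty list writes the header only."""
    path = Path(path)
    rows = []
    sidecar = []
    for i, am in enumerate(modules, start=1):
        base = am.base
        best_protein = None
        if am.protein_scores:
            best_protein = max(am.protein_scores, key=lambda p: (am.protein_scores[p], p))
        rows.append(
            {
                "module_id": i,
                "rel_score": round(base.module_score, 4),
                "interval": format_interval(base.chromosome, base.start_kb, base.end_kb),
                "n_signatures": len(base.signatures),
                "n_target_genes": len(am.target_genes),
                "primary_process": am.primary_process or "",
                "best_protein": best_protein or "",
                "causal_candidates": ",".join(g for g, _ in am.causal_candidates),
                "telomere_flag": am.telomere_flag,
            }
        )
        sidecar.append(
            {
                "module_id": i,
                "chromosome": base.chromosome,
                "start_kb": base.start_kb,
                "end_kb": base.end_kb,
                "marker_ids": list(base.marker_ids),
                "signatures": list(base.signatures),
                "module_score": base.module_score,
                "target_genes": sorted(am.target_genes),
                "protein_scores": {p: s for p, s in sorted(am.protein_scores.items())},
                "primary_process": am.primary_process,
                "enrichments": [[t, p] for t, p in am.enrichments],
                "causal_candidates": [
                    {"gene": g, "criteria": sorted(flags)} for g, flags in am.causal_candidates
                ],
                "telomere_flag": am.telomere_flag,
            }
        )
    cols = [
        "module_id", "rel_score", "interval", "n_signatures", "n_target_genes",
        "primary_process", "best_protein", "causal_candidates", "telomere_flag",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_module_report_json(path) -> list[dict]:
    with open(Path(path).with_suffix(".json"), encoding="utf-8") as fh:
        return json.load(fh)
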