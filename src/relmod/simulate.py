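"""Synthetic segregating-population data with planted regulatory modules.

The generator emulates a haploid two-parent cross: each segregant inherits,
per chromosome, a Markov chain of 0/1 parental alleles (first marker fair
Bernoulli, each subsequent marker switching parent with probability
``inter_marker_recomb``).  Expression of a planted module's member genes
shifts by ``effect_size`` with the causal marker's allele on top of Gaussian
noise; the same member genes are coherently shifted by ``delta`` in the
module's regulator signatures of the mutant compendium, against Gaussian
background.  Member genes are placed on chromosomes other than the causal
marker's so the trans-only (cis-exclusion) rule never removes true targets.
A machine-readable truth file supports recovery scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GenotypeMatrix,
    MarkerMap,
    SignatureCompendium,
    write_compendium,
    write_marker_map,
)

logger = logging.getLogger(__name__)


@dataclass
class PlantedModule:
    causal_marker: int              # global marker index
    member_genes: tuple[int, ...]   # gene indices
    effect_size: float = 1.0        # expression shift per allele (beta)
    signatures: tuple[int, ...] = (0,)   # regulator signature indices
    delta: float = 2.0              # log2 shift of members in those signatures

    def __post_init__(self):
        if self.effect_size == 0 or self.delta == 0:
            raise ValueError("planted effect sizes must be nonzero")
        if not self.signatures:
            raise ValueError("planted module needs >= 1 regulator signature")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a yeast-cross-sized design scaled to desk size: 112
    segregants, three 500 kb chromosomes of 100 evenly spaced markers each,
    adjacent-marker recombination probability 0.1, 1000 genes, 40 mutant
    signatures, and three planted modules of 40 member genes with expression
    effect 1.0 (noise SD 0.5) and signature shift 2.0 (noise SD 0.3).
    """

    n_segregants: int = 112
    chromosomes: tuple[tuple[str, int, float], ...] = (
        ("I", 100, 500.0), ("II", 100, 500.0), ("III", 100, 500.0),
    )
    inter_marker_recomb: float = 0.1
    n_genes: int = 1000
    n_signatures: int = 40
    planted: tuple[PlantedModule, ...] = ()
    noise_sd: float = 0.5
    signature_noise_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.inter_marker_recomb <= 0.5:
            raise ValueError("recombination probability must be in [0, 0.5]")
        if min(self.n_segregants, self.n_genes, self.n_signatures) < 1:
            raise ValueError("counts must be positive")
        n_markers = self.n_markers
        used: set[int] = set()
        for pm in self.planted:
            if not 0 <= pm.causal_marker < n_markers:
                raise ValueError("planted causal marker out of bounds")
            if max(pm.signatures) >= self.n_signatures:
                raise ValueError("planted signature index out of bounds")
            if max(pm.member_genes, default=-1) >= self.n_genes:
                raise ValueError("planted member gene index out of bounds")
            overlap = used & set(pm.member_genes)
            if overlap:
                raise ValueError("member genes overlap across planted modules")
            used |= set(pm.member_genes)

    @property
    def n_markers(self) -> int:
        return sum(n for _, n, _ in self.chromosomes)

    def marker_ids(self) -> list[str]:
        return [f"m{i:04d}" for i in range(self.n_markers)]

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def signature_ids(self) -> list[str]:
        return [f"sig{j:03d}" for j in range(self.n_signatures)]

    def segregant_ids(self) -> list[str]:
        return [f"seg{s:03d}" for s in range(self.n_segregants)]

    def marker_chromosomes(self) -> list[str]:
        out = []
        for label, n, _ in self.chromosomes:
            out.extend([label] * n)
        return out


def default_planted_config(rng_seed: int = 0) -> SimConfig:
    """Three planted modules, one per chromosome, 40 trans member genes and
    three regulator signatures each (two of the three mutants hitting the
    same protein)."""
    base = SimConfig(rng_seed=rng_seed)
    n_chrom = len(base.chromosomes)
    per_chrom = base.n_genes // n_chrom
    # genes laid out round-robin free; here contiguous blocks per chromosome
    def chrom_of_gene(g: int) -> int:
        return min(g // per_chrom, n_chrom - 1)

    rng = np.random.default_rng(rng_seed + 101)
    planted = []
    used: set[int] = set()
    offset = 0
    for i in range(3):
        causal = offset + base.chromosomes[i][1] // 2  # mid-chromosome marker
        offset += base.chromosomes[i][1]
        pool = [g for g in range(base.n_genes) if chrom_of_gene(g) != i and g not in used]
        members = tuple(sorted(rng.choice(pool, size=40, replace=False).tolist()))
        used |= set(members)
        planted.append(
            PlantedModule(
                causal_marker=causal,
                member_genes=members,
                effect_size=1.0,
                signatures=(3 * i, 3 * i + 1, 3 * i + 2),
                delta=2.0,
            )
        )
    return SimConfig(planted=tuple(planted), rng_seed=rng_seed)


def _gene_positions(config: SimConfig) -> pd.DataFrame:
    """Genes in contiguous equal blocks along the chromosomes, evenly spaced."""
    n_chrom = len(config.chromosomes)
    per = config.n_genes // n_chrom
    rows = []
    g = 0
    for ci, (label, _, length) in enumerate(config.chromosomes):
        count = per if ci < n_chrom - 1 else config.n_genes - per * (n_chrom - 1)
        for k in range(count):
            rows.append((f"g{g:04d}", label, round((k + 0.5) * length / count, 3)))
            g += 1
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "position_kb"]).set_index("gene_id")


def simulate_genotypes(config: SimConfig, rng=None):
    """Markov recombination along each chromosome -> (GenotypeMatrix, MarkerMap)."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    r = config.inter_marker_recomb
    blocks = []
    map_rows = []
    for label, n_markers, length in config.chromosomes:
        first = rng.random(config.n_segregants) < 0.5
        flips = rng.random((n_markers - 1, config.n_segregants)) < r
        calls = np.empty((n_markers, config.n_segregants), dtype=float)
        calls[0] = first
        state = first.copy()
        for i in range(1, n_markers):
            state = state ^ flips[i - 1]
            calls[i] = state
        blocks.append(calls)
        spacing = length / n_markers
        for i in range(n_markers):
            map_rows.append((label, round((i + 0.5) * spacing, 3)))
    calls = np.vstack(blocks)
    genotypes = GenotypeMatrix(
        calls=pd.DataFrame(calls, index=config.marker_ids(), columns=config.segregant_ids())
    )
    mmap = MarkerMap(
        table=pd.DataFrame(
            map_rows, columns=["chromosome", "position_kb"], index=config.marker_ids()
        )
    )
    return genotypes, mmap


def simulate_expression(genotypes: GenotypeMatrix, config: SimConfig, rng=None) -> ExpressionMatrix:
    """Member genes shift with the causal allele; everything else is noise."""
    rng = np.random.default_rng(config.rng_seed + 1) if rng is None else rng
    x = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_segregants))
    calls = genotypes.calls.to_numpy(dtype=float)
    for pm in config.planted:
        allele = calls[pm.causal_marker]
        x[list(pm.member_genes)] += pm.effect_size * allele[None, :]
    return ExpressionMatrix(
        values=pd.DataFrame(x, index=config.gene_ids(), columns=config.segregant_ids())
    )


def simulate_compendium(config: SimConfig, rng=None) -> SignatureCompendium:
    """Mutant signatures: members of a planted module shift by delta in that
    module's regulator signatures; all other cells are background noise."""
    rng = np.random.default_rng(config.rng_seed + 2) if rng is None else rng
    v = rng.normal(0.0, config.signature_noise_sd, size=(config.n_genes, config.n_signatures))
    protein_of = {f"sig{j:03d}": f"BGP{j:03d}" for j in range(config.n_signatures)}
    for i, pm in enumerate(config.planted):
        for rank, j in enumerate(pm.signatures):
            v[list(pm.member_genes), j] += pm.delta
            # two mutants of the same protein where a module has >= 2 signatures
            sub = "A" if rank < 2 else chr(ord("A") + rank - 1)
            protein_of[f"sig{j:03d}"] = f"REG{i + 1}{sub}"
    return SignatureCompendium(
        values=pd.DataFrame(v, index=config.gene_ids(), columns=config.signature_ids()),
        protein_of=protein_of,
    )


def simulation_truth(config: SimConfig) -> list[dict]:
    """Serializable description of the planted modules."""
    marker_ids = config.marker_ids()
    gene_ids = config.gene_ids()
    sig_ids = config.signature_ids()
    chroms = config.marker_chromosomes()
    out = []
    for i, pm in enumerate(config.planted):
        out.append(
            {
                "module": i + 1,
                "causal_marker": marker_ids[pm.causal_marker],
                "causal_marker_index": pm.causal_marker,
                "chromosome": chroms[pm.causal_marker],
                "member_genes": [gene_ids[g] for g in pm.member_genes],
                "signatures": [sig_ids[j] for j in pm.signatures],
                "effect_size": pm.effect_size,
                "delta": pm.delta,
            }
        )
    return out


def generate_dataset(config: SimConfig, out_dir, force: bool = False) -> dict[str, Path]:
    """Write the full synthetic bundle (all TSV inputs + truth JSON).

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    genotypes, mmap = simulate_genotypes(config, rng)
    expression = simulate_expression(genotypes, config, rng)
    compendium = simulate_compendium(config, rng)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "marker_map": out / "marker_map.tsv",
        "expression": out / "expression.tsv",
        "compendium": out / "compendium.tsv",
        "compendium_meta": out / "compendium_meta.tsv",
        "gene_positions": out / "gene_positions.tsv",
        "chrom_lengths": out / "chrom_lengths.tsv",
        "truth": out / "truth.json",
    }
    genotypes.calls.astype("Int64").to_csv(paths["genotypes"], sep="\t", na_rep="NA")
    write_marker_map(mmap, paths["marker_map"])
    expression.values.to_csv(paths["expression"], sep="\t", na_rep="NA", float_format="%.6g")
    write_compendium(compendium, paths["compendium"], paths["compendium_meta"])
    _gene_positions(config).to_csv(paths["gene_positions"], sep="\t")
    pd.DataFrame(
        [(label, length) for label, _, length in config.chromosomes],
        columns=["chromosome", "length_kb"],
    ).to_csv(paths["chrom_lengths"], sep="\t", index=False)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump({"config": _config_dict(config), "modules": simulation_truth(config)}, fh, indent=1)
    logger.info("simulate: wrote dataset (%d markers, %d genes, %d signatures) to %s",
                config.n_markers, config.n_genes, config.n_signatures, out)
    return paths


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["chromosomes"] = [list(c) for c in config.chromosomes]
    d["planted"] = [asdict(pm) for pm in config.planted]
    return d
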