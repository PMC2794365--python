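import numpy as np
import pandas as pd
import pytest

import relmod
from relmod.biclust import ReLModule
from relmod.relscore import ReLMatrix
from relmod.simulate import PlantedModule, SimConfig, _gene_positions


@pytest.fixture(scope="session")
def small_config():
    """One planted module on a two-chromosome toy cross (members trans)."""
    return SimConfig(
        n_segregants=60,
        chromosomes=(("I", 30, 150.0), ("II", 30, 150.0)),
        n_genes=150,
        n_signatures=8,
        planted=(
            PlantedModule(
                causal_marker=15,
                member_genes=tuple(range(100, 120)),  # chromosome II block
                effect_size=1.0,
                signatures=(0, 1),
                delta=2.0,
            ),
        ),
        rng_seed=11,
    )


class Bundle:
    def __init__(self, cfg):
        self.cfg = cfg
        self.genotypes, self.marker_map = relmod.simulate_genotypes(cfg)
        self.expression = relmod.simulate_expression(self.genotypes, cfg)
        self.compendium = relmod.simulate_compendium(cfg)
        self.linkage = relmod.compute_linkage_matrix(self.genotypes, self.expression)
        self.rel = relmod.compute_rel_matrix(self.linkage, self.compendium, self.marker_map)
        self.gene_positions = _gene_positions(cfg)
        self.truth = relmod.simulate.simulation_truth(cfg)


@pytest.fixture(scope="session")
def small_run(small_config):
    return Bundle(small_config)


@pytest.fixture(scope="session")
def default_run():
    """Full-size default study conditions, one seed; shared by slow tests."""
    bundle = Bundle(relmod.default_planted_config(7))
    bundle.modules = relmod.find_modules(bundle.rel)
    return bundle


def make_rel_matrix(scores: np.ndarray, marker_chrom) -> ReLMatrix:
    """Minimal ReLMatrix around a raw score grid for biclustering tests."""
    scores = np.asarray(scores, dtype=float)
    M, S = scores.shape
    return ReLMatrix(
        marker_ids=[f"m{i}" for i in range(M)],
        signature_ids=[f"s{j}" for j in range(S)],
        gene_ids=[],
        marker_chrom=list(marker_chrom),
        marker_pos=np.arange(M, dtype=float),
        rel_score=scores,
        neg_log10_p=scores.copy(),
        direction=np.zeros((M, S), np.int8),
        threshold=np.zeros((M, S)),
        hypergeom_p=np.ones((M, S)),
        n_high=np.zeros((M, S), np.int32),
        hit_genes={},
        n_tests=M * S,
    )


def make_module(start, end, sig_idx, score, chrom="I", start_kb=None, end_kb=None):
    sig_idx = tuple(sig_idx)
    return ReLModule(
        chromosome=chrom,
        start=start,
        end=end,
        marker_ids=tuple(f"m{i}" for i in range(start, end + 1)),
        signatures=tuple(f"s{j}" for j in sig_idx),
        signature_idx=sig_idx,
        module_score=score,
        start_kb=float(start if start_kb is None else start_kb),
        end_kb=float(end if end_kb is None else end_kb),
    )
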