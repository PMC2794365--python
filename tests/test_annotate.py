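from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from relmod.annotate import (
    causal_candidates,
    cis_gene_set,
    enrich,
    protein_scores,
    target_genes,
    telomere_flag,
)
from relmod.io import AnnotationSet
from tests.conftest import make_module, make_rel_matrix


def hypergeom_tail_exact(k, N, K, n) -> float:
    """Exact rational upper-tail P(X >= k) via binomial coefficients."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


def positions(n=120, chrom="I", spacing=1.0):
    return pd.DataFrame(
        {
            "chromosome": [chrom] * n,
            "position_kb": [spacing * (i + 1) for i in range(n)],
        },
        index=[f"g{i:03d}" for i in range(n)],
    )


class TestTargetGenes:
    def _module(self):
        # one marker x five signatures => 5 entries; interval I:200-210 kb,
        # far from every positioned gene (all within 120 kb)
        return make_module(0, 0, tuple(range(5)), 5.0, start_kb=200.0, end_kb=210.0)

    def _hits(self, gene_in_n_entries: dict):
        mod = self._module()
        hits = {}
        for idx, s in enumerate(mod.signatures):
            present = {g for g, n in gene_in_n_entries.items() if idx < n}
            hits[("m0", s)] = frozenset(present)
        return mod, hits

    def test_exactly_sixty_percent_is_included(self):
        mod, hits = self._hits({"g000": 3, "g001": 2, "g002": 5})
        got = target_genes(mod, hits, positions())
        assert got == {"g000", "g002"}  # 3/5 = 60% in, 2/5 out

    def test_cis_window_rule(self):
        # interval covers genes g050..g052 (positions 51-53 kb)
        mod = make_module(0, 0, (0,), 5.0, start_kb=50.5, end_kb=53.5)
        hits = {("m0", "s0"): frozenset(positions().index)}
        got = target_genes(mod, hits, positions())
        # 29 genes away from the boundary gene g052 -> excluded;
        # 30 genes away -> included
        assert "g081" not in got  # 81 - 52 = 29
        assert "g082" in got      # 82 - 52 = 30
        assert "g042" not in got  # 8 genes upstream of g050
        assert "g000" in got      # 50 genes upstream
        for g in ("g050", "g051", "g052"):
            assert g not in got

    def test_unpositioned_gene_retained_with_warning(self, caplog):
        mod = make_module(0, 0, (0,), 5.0, start_kb=50.5, end_kb=53.5)
        hits = {("m0", "s0"): frozenset({"ghost"})}
        with caplog.at_level("WARNING"):
            got = target_genes(mod, hits, positions())
        assert "ghost" in got
        assert any("cannot be cis-excluded" in r.message for r in caplog.records)

    def test_cis_set_when_interval_holds_no_gene(self):
        # interval between g049 (50 kb) and g050 (51 kb): nearest outside
        # genes count as 1 away on each side
        cis = cis_gene_set(positions(), "I", 50.2, 50.8, cis_gene_window=3)
        assert cis == {"g048", "g049", "g050", "g051"}


class TestProteinScores:
    def test_single_signature_interval_mean(self):
        rel = make_rel_matrix(np.array([[4.0], [6.0]]), ["I", "I"])
        mod = make_module(0, 1, (0,), 5.0)
        assert protein_scores(mod, rel, {"s0": "P1"}) == {"P1": 5.0}

    def test_two_signatures_same_protein(self):
        # hand-computed 2x2: sig means over the interval are 2.0 and 4.0
        rel = make_rel_matrix(np.array([[1.0, 3.0], [3.0, 5.0]]), ["I", "I"])
        mod = make_module(0, 1, (0, 1), 3.0)
        got = protein_scores(mod, rel, {"s0": "P1", "s1": "P1"})
        assert got == {"P1": pytest.approx(3.0)}

    def test_covers_exactly_module_proteins(self):
        rel = make_rel_matrix(np.ones((2, 3)) * 4, ["I", "I"])
        mod = make_module(0, 1, (0, 2), 4.0)
        got = protein_scores(mod, rel, {"s0": "P1", "s1": "P2", "s2": "P3"})
        assert set(got) == {"P1", "P3"}


class TestEnrich:
    def _annotation(self, terms, universe):
        return AnnotationSet(
            terms={t: frozenset(g) for t, g in terms.items()},
            universe=frozenset(universe),
        )

    def test_matches_exact_combinatorial_oracle(self):
        universe = [f"g{i}" for i in range(20)]
        ann = self._annotation({"T1": universe[:5]}, universe)
        targets = universe[:3] + [universe[10]]  # overlap 3 of term's 5
        hits, primary = enrich(targets, ann, alpha=0.05)
        expected = hypergeom_tail_exact(3, 20, 5, 4)
        assert expected == pytest.approx(155 / 4845, rel=1e-12)
        assert primary == "T1"
        assert hits[0][1] == pytest.approx(expected, rel=1e-12)

    def test_term_equal_to_universe_is_never_significant(self):
        universe = [f"g{i}" for i in range(20)]
        ann = self._annotation({"ALL": universe}, universe)
        hits, primary = enrich(universe[:4], ann, alpha=0.05)
        assert hits == [] and primary is None  # P = 1 exactly

    def test_primary_is_smallest_corrected_p(self):
        universe = [f"g{i}" for i in range(40)]
        ann = self._annotation(
            {"Tweak": universe[:10], "Tstrong": universe[:5]}, universe
        )
        hits, primary = enrich(universe[:5], ann, alpha=0.05)
        assert primary == "Tstrong"
        assert [t for t, _ in hits][0] == "Tstrong"

    def test_empty_target_set(self):
        ann = self._annotation({"T1": ["g1"]}, ["g1", "g2"])
        assert enrich([], ann) == ([], None)

    def test_pvalues_super_uniform_under_random_draws(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(60)]
        ann = self._annotation({"T1": universe[:15]}, universe)
        raw = []
        for _ in range(1000):
            draw = rng.choice(universe, size=8, replace=False)
            hits, _ = enrich(draw, ann, alpha=1.0000001)  # keep every tested term
            raw.append(hits[0][1])
        raw = np.asarray(raw)
        for alpha in (0.01, 0.05, 0.2, 0.5):
            frac = (raw <= alpha).mean()
            assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 1000)


class TestCausalCandidates:
    def _setup(self):
        gp = positions()
        mod = make_module(0, 0, (0,), 5.0, start_kb=50.5, end_kb=53.5)
        targets = [f"g{i:03d}" for i in range(100, 112)]
        universe = list(gp.index)
        ann = AnnotationSet(
            terms={"sporulation": frozenset(targets + ["g051"])},
            universe=frozenset(universe),
        )
        net = nx.Graph()
        net.add_edge("g051", "P1", kind="protein-protein")
        return mod, gp, ann, net, targets

    def test_process_and_interaction_flags_rank_first(self):
        mod, gp, ann, net, targets = self._setup()
        binding = {"g052": frozenset(targets[:8])}
        got = causal_candidates(
            mod, gp, ann, net, binding, targets, "sporulation", {"P1"}
        )
        assert got[0][0] == "g051"
        assert got[0][1] == {"process", "interaction"}
        flags = dict(got)
        assert flags["g052"] == {"binding"}

    def test_no_candidate_when_no_criterion_met(self):
        mod, gp, ann, _, targets = self._setup()
        got = causal_candidates(
            mod, gp, ann, nx.Graph(), None, targets, "other_process", {"P9"}
        )
        assert got == []

    @pytest.mark.parametrize("overlap", [0, 2, 5, 8, 10])
    def test_binding_criterion_matches_hypergeometric_oracle(self, overlap):
        gp = positions(30)
        mod = make_module(0, 0, (0,), 5.0, start_kb=9.5, end_kb=10.5)  # gene g009
        universe = list(gp.index)
        targets = universe[15:25]
        ann = AnnotationSet(terms={}, universe=frozenset(universe))
        bound = frozenset(targets[:overlap] + universe[:10 - overlap])
        got = causal_candidates(
            mod, gp, ann, None, {"g009": bound}, targets, None, set()
        )
        p = stats.hypergeom.sf(overlap - 1, 30, 10, 10)  # single test: no correction
        if p < 0.05:
            assert got == [("g009", frozenset({"binding"}))]
        else:
            assert got == []

    def test_stable_under_input_row_order(self):
        mod, gp, ann, net, targets = self._setup()
        shuffled = gp.sample(frac=1.0, random_state=4)
        a = causal_candidates(mod, gp, ann, net, None, targets, "sporulation", {"P1"})
        b = causal_candidates(mod, shuffled, ann, net, None, targets, "sporulation", {"P1"})
        assert a == b


class TestTelomereFlag:
    def _gp(self, rows):
        return pd.DataFrame(
            rows, columns=["chromosome", "position_kb"],
            index=[f"t{i}" for i in range(len(rows))],
        )

    def test_mid_chromosome_targets_not_flagged(self):
        gp = self._gp([("I", 250.0), ("II", 260.0), ("III", 240.0), ("IV", 255.0)])
        lengths = {c: 500.0 for c in ["I", "II", "III", "IV"]}
        assert not telomere_flag(gp.index, gp, lengths)

    def test_multi_chromosome_telomeric_majority_flagged(self):
        rows = [("I", 10.0), ("II", 495.0), ("III", 5.0), ("IV", 480.0),
                ("I", 250.0), ("II", 250.0)]
        gp = self._gp(rows)
        lengths = {c: 500.0 for c in ["I", "II", "III", "IV"]}
        # 4/6 targets telomeric on 4 chromosomes
        assert telomere_flag(gp.index, gp, lengths)

    def test_boundary_exactly_at_window_counts(self):
        rows = [("I", 30.0), ("II", 470.0), ("III", 30.0)]
        gp = self._gp(rows)
        lengths = {c: 500.0 for c in ["I", "II", "III"]}
        assert telomere_flag(gp.index, gp, lengths, telomere_kb=30.0, min_chroms=3)

    def test_few_chromosomes_not_flagged(self):
        rows = [("I", 10.0), ("I", 5.0), ("II", 495.0)]
        gp = self._gp(rows)
        lengths = {"I": 500.0, "II": 500.0}
        assert not telomere_flag(gp.index, gp, lengths)
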