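import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from relmod.relscore import (
    DegenerateSignatureError,
    bonferroni_factor,
    rel_entry,
    select_threshold,
    split_signature,
    threshold_sensitivity,
)


def brute_force_select(linkage_column: pd.Series, over_set, under_set):
    """Exhaustive scan oracle: every observed value x both directions, scipy
    hypergeometric tail, ties to the smaller threshold then 'up'."""
    genes = list(linkage_column.index)
    s = linkage_column.to_numpy(dtype=float)
    N = len(genes)
    best = (np.inf, None, None)
    for t in sorted(set(s.tolist())):
        high = s >= t
        n = int(high.sum())
        for direction, grp in (("up", over_set), ("down", under_set)):
            if not grp:
                continue
            k = sum(1 for g, h in zip(genes, high) if h and g in grp)
            p = float(stats.hypergeom.sf(k - 1, N, len(grp), n))
            if p < best[0]:
                best = (p, t, direction)
    return best[1], best[2], best[0]


def _planted_column(n_genes=500, n_block=20, over_size=50, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    scores = np.zeros(n_genes)
    scores[:n_block] = 5.0
    over = frozenset(genes[:over_size])
    under = frozenset(genes[over_size : 2 * over_size])
    col = pd.Series(scores, index=genes)
    return col, over, under


class TestSplitSignature:
    def test_symmetric_three_values(self):
        v = pd.Series([-1.0, 0.0, 1.0], index=["g1", "g2", "g3"])
        over, under, mean = split_signature(v)
        assert over == {"g3"} and under == {"g1"} and mean == 0.0

    def test_constant_signature_is_degenerate(self):
        with pytest.raises(DegenerateSignatureError):
            split_signature(pd.Series([5.0] * 4, index=list("abcd")))

    def test_gaussian_split_is_near_even_and_exhaustive(self):
        rng = np.random.default_rng(1)
        v = pd.Series(rng.normal(size=1000), index=[f"g{i}" for i in range(1000)])
        over, under, _ = split_signature(v)
        assert len(over) + len(under) == 1000  # continuous: no exact ties
        assert abs(len(over) - 500) < 4 * np.sqrt(250)

    def test_missing_values_in_neither_group(self):
        v = pd.Series([1.0, -1.0, np.nan, 0.5], index=list("abcd"))
        over, under, _ = split_signature(v)
        assert "c" not in over and "c" not in under


class TestSelectThreshold:
    def test_planted_block(self):
        col, over, under = _planted_column()
        t, d, p = select_threshold(col, over, under)
        assert t == 5.0 and d == "up"
        _, _, p_oracle = brute_force_select(col, over, under)
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_single_observed_value(self):
        genes = [f"g{i}" for i in range(20)]
        col = pd.Series(np.ones(20), index=genes)
        t, d, _ = select_threshold(col, frozenset(genes[:5]), frozenset(genes[5:10]))
        assert t == 1.0

    @pytest.mark.parametrize("seed", range(50))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(20, 80))
        genes = [f"g{i}" for i in range(n)]
        # mix of ties and continuous values
        scores = np.where(rng.random(n) < 0.4, rng.integers(0, 4, n), rng.random(n) * 4)
        labels = rng.choice(3, n)
        over = frozenset(g for g, l in zip(genes, labels) if l == 0)
        under = frozenset(g for g, l in zip(genes, labels) if l == 1)
        if not over and not under:
            over = frozenset(genes[:3])
        col = pd.Series(scores.astype(float), index=genes)
        got = select_threshold(col, over, under)
        expected = brute_force_select(col, over, under)
        assert got[0] == expected[0] and got[1] == expected[1]
        assert got[2] == pytest.approx(expected[2], rel=1e-12)

    def test_both_groups_empty_errors(self):
        col, _, _ = _planted_column()
        with pytest.raises(ValueError, match="empty"):
            select_threshold(col, frozenset(), frozenset())


class TestRelEntry:
    def _fixture(self, seed=4, shift=2.0, n_high=20, n_rest=480):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_high + n_rest)]
        scores = np.concatenate([np.full(n_high, 5.0), np.zeros(n_rest)])
        values = rng.normal(size=n_high + n_rest)
        values[:n_high] += shift
        return (
            pd.Series(scores, index=genes),
            pd.Series(values, index=genes),
        )

    def test_matches_textbook_welch_oracle(self):
        col, sig = self._fixture()
        n_tests = 1000
        entry = rel_entry("m", "s", col, sig, n_tests)
        a = sig.to_numpy()[:20]
        b = sig.to_numpy()[20:]
        # independent Welch computation: explicit means/variances + t tail
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2a, se2b = va / len(a), vb / len(b)
        tval = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1))
        p = 2 * stats.t.sf(abs(tval), df)
        expected = -math.log10(min(1.0, p * n_tests))
        assert entry.rel_score == pytest.approx(expected, abs=1e-8)
        assert entry.direction == "up"
        assert entry.threshold == 5.0

    def test_identical_distributions_floor_at_zero(self):
        col, sig = self._fixture(shift=0.0, seed=8)
        entry = rel_entry("m", "s", col, sig, n_tests=500 * 40)
        assert entry.rel_score == 0.0

    def test_bonferroni_factor_and_correction_shift(self):
        assert bonferroni_factor(2956, 283) == 836548
        col, sig = self._fixture()
        e1 = rel_entry("m", "s", col, sig, n_tests=1)
        e2 = rel_entry("m", "s", col, sig, n_tests=836548)
        assert e1.rel_score - e2.rel_score == pytest.approx(math.log10(836548), abs=1e-8)

    def test_hit_genes_follow_direction(self):
        col, sig = self._fixture()
        entry = rel_entry("m", "s", col, sig, n_tests=100)
        mean = sig.mean()
        high = set(col.index[col >= entry.threshold])
        assert entry.hit_genes <= high
        assert all(sig[g] > mean for g in entry.hit_genes)

    def test_degenerate_signature_scores_zero(self):
        col, _ = self._fixture()
        sig = pd.Series(np.zeros(len(col)), index=col.index)
        entry = rel_entry("m", "s", col, sig, n_tests=10)
        assert entry.rel_score == 0.0 and entry.direction is None

    def test_monotone_transform_invariance(self):
        col, sig = self._fixture(seed=12)
        base = rel_entry("m", "s", col, sig, 100)
        transformed = col**3 + 2.0  # strictly monotone, tie-preserving
        other = rel_entry("m", "s", transformed, sig, 100)
        assert other.rel_score == pytest.approx(base.rel_score, abs=1e-9)
        assert other.direction == base.direction
        assert other.hit_genes == base.hit_genes


class TestRelMatrix:
    def test_cardinality_and_completeness(self, small_run):
        rel = small_run.rel
        M, S = rel.shape
        assert rel.n_entries == M * S == rel.n_tests
        assert np.all(np.isfinite(rel.rel_score)) and np.all(rel.rel_score >= 0)

    def test_markers_in_genomic_order(self, small_run):
        rel = small_run.rel
        mm = small_run.marker_map
        assert rel.marker_ids == mm.genomic_order(rel.marker_ids)

    def test_composition_equals_rel_entry(self, small_run):
        rel = small_run.rel
        lmat = small_run.linkage
        comp = small_run.compendium
        rng = np.random.default_rng(0)
        for _ in range(6):
            i = int(rng.integers(0, rel.shape[0]))
            j = int(rng.integers(0, rel.shape[1]))
            col = lmat.scores.loc[rel.marker_ids[i]].reindex(rel.gene_ids)
            sig = comp.values[rel.signature_ids[j]].reindex(rel.gene_ids)
            e = rel_entry(rel.marker_ids[i], rel.signature_ids[j], col, sig, rel.n_tests)
            got = rel.entry(i, j)
            assert got.rel_score == pytest.approx(e.rel_score, abs=1e-8)
            assert got.direction == e.direction
            assert got.threshold == e.threshold
            assert got.hit_genes == e.hit_genes

    def test_planted_entry_is_significant(self, small_run):
        rel = small_run.rel
        truth = small_run.truth[0]
        i = rel.marker_ids.index(truth["causal_marker"])
        for s in truth["signatures"]:
            j = rel.signature_ids.index(s)
            assert rel.rel_score[i, j] > 3.0
            assert rel.direction[i, j] == 1  # members are over-expressed

    def test_hit_direction_invariant_across_entries(self, small_run):
        rel = small_run.rel
        comp = small_run.compendium
        rng = np.random.default_rng(3)
        for _ in range(10):
            i = int(rng.integers(0, rel.shape[0]))
            j = int(rng.integers(0, rel.shape[1]))
            e = rel.entry(i, j)
            if e.direction is None or not e.hit_genes:
                continue
            sig = comp.values[e.signature_id].reindex(rel.gene_ids)
            mean = sig[np.isfinite(sig.to_numpy())].mean()
            vals = sig[list(e.hit_genes)]
            assert (vals > mean).all() if e.direction == "up" else (vals < mean).all()

    def test_save_load_round_trip(self, small_run, tmp_path):
        rel = small_run.rel
        rel.save(tmp_path / "rel")
        back = type(rel).load(tmp_path / "rel")
        np.testing.assert_allclose(back.rel_score, rel.rel_score)
        np.testing.assert_array_equal(back.direction, rel.direction)
        assert back.marker_ids == rel.marker_ids
        assert back.hit_gene_sets() == rel.hit_gene_sets()

    def test_shared_gene_floor_enforced(self, small_run):
        from relmod.relscore import compute_rel_matrix

        comp = small_run.compendium
        trimmed = type(comp)(
            values=comp.values.iloc[:50], protein_of=dict(comp.protein_of)
        )
        with pytest.raises(ValueError, match="shared"):
            compute_rel_matrix(small_run.linkage, trimmed, small_run.marker_map)


class TestThresholdSensitivity:
    def test_adjacent_thresholds_do_not_flip_planted_significance(self):
        rng = np.random.default_rng(5)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        scores = rng.random(n)
        scores[:25] += 4.0  # planted high-linkage block
        values = rng.normal(size=n)
        values[:25] += 2.0
        col = pd.Series(scores, index=genes)
        sig = pd.Series(values, index=genes)
        report = threshold_sensitivity(col, sig, n_tests=1000)
        chosen = report[report["which"] == "chosen"]["rel_score"].iloc[0]
        assert chosen > 3.0
        assert (report["rel_score"] > 3.0).all()
        assert (report["rel_score"] - chosen).abs().max() < chosen
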