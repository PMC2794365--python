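"""The ReL (regulatory-linkage) test.

For one genetic marker and one regulatory signature:

1. Split the signature's genes into over-expressed (value > signature mean)
   and under-expressed (value < mean) groups.
2. Scan every observed eQTL likelihood value as a candidate threshold; for
   each threshold and each group, score the over-representation of
   high-linkage genes (score >= threshold) in the group with a hypergeometric
   upper tail.  The best (threshold, direction) pair defines the
   high-linkage gene set; ties prefer the smaller threshold, then "up".
3. Compare signature values of high-linkage genes against all remaining
   scored genes with Welch's two-sample t-test.  The ReL score is
   -log10 of the Bonferroni-corrected two-sided P (corrected over all
   marker x signature pairs of the run), floored at 0.
4. Hit genes are the high-linkage genes on the chosen side of the signature
   mean; they feed module target-gene derivation.

Degenerate pairs (constant signature, or a subset with fewer than two
members) score 0 and are flagged, so biclustering always sees a complete
finite matrix.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._hypergeom import sf_batch
from .io import MarkerMap, SignatureCompendium
from .linkage import LinkageMatrix

logger = logging.getLogger(__name__)

MIN_SCAN_GENES = 10
MIN_SHARED_GENES = 100
_LN10 = math.log(10.0)


class DegenerateSignatureError(ValueError):
    """All finite signature values are identical; no over/under split exists."""


def bonferroni_factor(n_markers: int, n_signatures: int) -> int:
    """Number of ReL tests in a run: every marker against every signature."""
    return int(n_markers) * int(n_signatures)


def split_signature(signature_values: pd.Series):
    """Partition genes by the signature mean.

    Returns (over_set, under_set, mean); genes exactly at the mean belong to
    neither group, genes with missing values to neither group.
    """
    v = signature_values.astype(float)
    finite = v[np.isfinite(v.to_numpy())]
    if len(finite) < 2 or finite.nunique() < 2:
        raise DegenerateSignatureError("signature has fewer than 2 distinct finite values")
    mean = float(finite.mean())
    over = frozenset(finite.index[finite > mean])
    under = frozenset(finite.index[finite < mean])
    return over, under, mean


def _choose_best(p: np.ndarray, ss, block_end, n_high, k_mat):
    """Pick the scan winner from a (T, 2) P grid (columns = up, down).

    Ties prefer the smaller threshold (the later candidate block), then the
    "up" direction.
    """
    best = p.min()
    rows = np.nonzero((p[:, 0] == best) | (p[:, 1] == best))[0]
    b = rows[-1]
    d = 0 if p[b, 0] == best else 1
    return (
        float(ss[block_end[b]]),
        "up" if d == 0 else "down",
        int(n_high[b]),
        int(k_mat[b, d]),
        float(best),
    )


def _scan_sorted(ss, block_end, n_high, mem_sorted, n_universe, k_over, k_under):
    """Core threshold scan on a pre-sorted linkage column.

    ss: scores sorted descending; block_end: index of the last element of each
    tie block (candidate thresholds are ss[block_end]); n_high = block_end+1;
    mem_sorted: (G, 2) bool, columns = (over, under) membership in sorted
    order.  Returns (threshold, direction, n_high_chosen, k_chosen, p_scan).
    """
    cs = np.cumsum(mem_sorted, axis=0)
    k_mat = cs[block_end]  # (T, 2)
    T = len(block_end)
    p = np.full((T, 2), np.inf)
    if k_over > 0:
        p[:, 0] = sf_batch(k_mat[:, 0], n_universe, np.full(T, k_over), n_high)
    if k_under > 0:
        p[:, 1] = sf_batch(k_mat[:, 1], n_universe, np.full(T, k_under), n_high)
    return _choose_best(p, ss, block_end, n_high, k_mat)


def _sort_blocks(scores: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    ss = scores[order]
    last = np.nonzero(np.diff(ss) != 0)[0]
    block_end = np.append(last, len(ss) - 1)
    n_high = block_end + 1
    return order, ss, block_end, n_high


def select_threshold(linkage_column: pd.Series, over_set, under_set):
    """Choose the eQTL likelihood threshold for one (marker, signature) pair.

    Considers every observed linkage value as an inclusive (score >= t)
    threshold and both expression groups; returns the triple
    (threshold, direction, hypergeom_p) minimizing the hypergeometric
    upper-tail P of the overlap between high-linkage genes and the group.
    """
    s = linkage_column.astype(float)
    genes = s.index
    if len(genes) < MIN_SCAN_GENES:
        raise ValueError(f"need >= {MIN_SCAN_GENES} scored genes, got {len(genes)}")
    over = np.fromiter((g in over_set for g in genes), bool, len(genes))
    under = np.fromiter((g in under_set for g in genes), bool, len(genes))
    k_over, k_under = int(over.sum()), int(under.sum())
    if k_over == 0 and k_under == 0:
        raise ValueError("both expression groups are empty")
    sv = s.to_numpy()
    order, ss, block_end, n_high = _sort_blocks(sv)
    mem = np.column_stack([over[order], under[order]])
    t, direction, n_hi, k, _ = _scan_sorted(
        ss, block_end, n_high, mem, len(genes), k_over, k_under
    )
    kk = k_over if direction == "up" else k_under
    p = float(stats.hypergeom.sf(k - 1, len(genes), kk, n_hi))
    return t, direction, p


@dataclass
class ReLEntry:
    marker_id: str
    signature_id: str
    rel_score: float
    direction: str | None  # "up" / "down" / None for degenerate entries
    threshold: float
    hypergeom_p: float
    hit_genes: frozenset[str]
    n_high_linkage: int
    note: str = ""


def _welch_rel_score(a: np.ndarray, b: np.ndarray, n_tests: int) -> float:
    """-log10 of the Bonferroni-corrected two-sided Welch P, floored at 0.

    Computed on the log scale (t.logsf) so strongly separated groups do not
    underflow to an infinite score.
    """
    res = stats.ttest_ind(a, b, equal_var=False)
    logp = math.log(2.0) + stats.t.logsf(abs(float(res.statistic)), float(res.df))
    log10_pcorr = (logp + math.log(n_tests)) / _LN10
    return max(0.0, -log10_pcorr)


def rel_entry(
    marker_id: str,
    signature_id: str,
    linkage_column: pd.Series,
    signature_values: pd.Series,
    n_tests: int,
) -> ReLEntry:
    """Full ReL test for one (marker, signature) pair."""
    sig = signature_values.reindex(linkage_column.index).astype(float)
    try:
        over, under, mean = split_signature(sig)
    except DegenerateSignatureError:
        return ReLEntry(
            marker_id, signature_id, 0.0, None, float("nan"), 1.0,
            frozenset(), 0, note="degenerate signature",
        )
    t, direction, p_hyp = select_threshold(linkage_column, over, under)
    return _entry_at_threshold(
        marker_id, signature_id, linkage_column, sig, mean,
        t, direction, p_hyp, n_tests,
    )


def _entry_at_threshold(
    marker_id, signature_id, linkage_column, sig, mean,
    t, direction, p_hyp, n_tests,
) -> ReLEntry:
    sv = linkage_column.to_numpy(dtype=float)
    vv = sig.to_numpy(dtype=float)
    high = sv >= t
    finite = np.isfinite(vv)
    a = vv[high & finite]
    b = vv[~high & finite]
    n_hi = int(high.sum())
    if len(a) < 2 or len(b) < 2:
        return ReLEntry(
            marker_id, signature_id, 0.0, direction, t, p_hyp,
            frozenset(), n_hi, note="subset smaller than 2",
        )
    score = _welch_rel_score(a, b, n_tests)
    if direction == "up":
        hit = high & finite & (vv > mean)
    else:
        hit = high & finite & (vv < mean)
    return ReLEntry(
        marker_id, signature_id, score, direction, t, p_hyp,
        frozenset(linkage_column.index[hit]), n_hi,
    )


def rel_entry_at_threshold(
    marker_id, signature_id, linkage_column, signature_values, threshold,
    direction, n_tests,
) -> ReLEntry:
    """ReL test with a caller-imposed threshold (used by the sensitivity report)."""
    sig = signature_values.reindex(linkage_column.index).astype(float)
    over, under, mean = split_signature(sig)
    genes = linkage_column.index
    high = linkage_column.to_numpy(dtype=float) >= threshold
    group = over if direction == "up" else under
    k = sum(1 for g in genes[high] if g in group)
    p_hyp = float(stats.hypergeom.sf(k - 1, len(genes), len(group), int(high.sum())))
    return _entry_at_threshold(
        marker_id, signature_id, linkage_column, sig, mean,
        threshold, direction, p_hyp, n_tests,
    )


def threshold_sensitivity(linkage_column, signature_values, n_tests) -> pd.DataFrame:
    """Re-score one pair at the chosen threshold and at the adjacent observed
    linkage values on either side — a small robustness report for the
    threshold scan."""
    entry = rel_entry("m", "s", linkage_column, signature_values, n_tests)
    observed = np.unique(linkage_column.to_numpy(dtype=float))
    i = int(np.searchsorted(observed, entry.threshold))
    rows = []
    for j, label in ((i - 1, "below"), (i, "chosen"), (i + 1, "above")):
        if 0 <= j < len(observed):
            e = rel_entry_at_threshold(
                "m", "s", linkage_column, signature_values,
                float(observed[j]), entry.direction, n_tests,
            )
            rows.append(
                {"which": label, "threshold": e.threshold, "rel_score": e.rel_score,
                 "n_high_linkage": e.n_high_linkage}
            )
    return pd.DataFrame(rows)


@dataclass
class ReLMatrix:
    """Complete markers x signatures grid of ReL test results.

    Markers are stored in genomic order.  Per-entry scalars live in dense
    arrays; hit-gene sets are kept as index arrays into ``gene_ids``.
    """

    marker_ids: list[str]
    signature_ids: list[str]
    gene_ids: list[str]
    marker_chrom: list[str]
    marker_pos: np.ndarray
    rel_score: np.ndarray       # (M, S) float, Bonferroni-corrected
    neg_log10_p: np.ndarray     # (M, S) float, uncorrected -log10 t-test P
    direction: np.ndarray       # (M, S) int8: +1 up, -1 down, 0 degenerate
    threshold: np.ndarray       # (M, S) float
    hypergeom_p: np.ndarray     # (M, S) float
    n_high: np.ndarray          # (M, S) int32
    hit_genes: dict = field(repr=False, default_factory=dict)  # (i, j) -> int array
    n_tests: int = 0

    @property
    def shape(self):
        return self.rel_score.shape

    @property
    def n_entries(self) -> int:
        return int(self.rel_score.size)

    def entry(self, i: int, j: int) -> ReLEntry:
        d = {1: "up", -1: "down", 0: None}[int(self.direction[i, j])]
        hits = self.hit_genes.get((i, j), np.empty(0, int))
        return ReLEntry(
            marker_id=self.marker_ids[i],
            signature_id=self.signature_ids[j],
            rel_score=float(self.rel_score[i, j]),
            direction=d,
            threshold=float(self.threshold[i, j]),
            hypergeom_p=float(self.hypergeom_p[i, j]),
            hit_genes=frozenset(self.gene_ids[g] for g in hits),
            n_high_linkage=int(self.n_high[i, j]),
        )

    def hit_gene_sets(self) -> dict:
        """(marker_id, signature_id) -> frozenset of hit gene ids."""
        return {
            (self.marker_ids[i], self.signature_ids[j]):
                frozenset(self.gene_ids[g] for g in idx)
            for (i, j), idx in self.hit_genes.items()
        }

    # -- persistence (TSV scores + JSON sidecar) ---------------------------

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        pd.DataFrame(
            self.rel_score, index=self.marker_ids, columns=self.signature_ids
        ).to_csv(prefix.with_suffix(".scores.tsv"), sep="\t")
        sidecar = {
            "marker_ids": self.marker_ids,
            "signature_ids": self.signature_ids,
            "gene_ids": self.gene_ids,
            "marker_chrom": self.marker_chrom,
            "marker_pos": self.marker_pos.tolist(),
            "neg_log10_p": self.neg_log10_p.tolist(),
            "direction": self.direction.tolist(),
            "threshold": self.threshold.tolist(),
            "hypergeom_p": self.hypergeom_p.tolist(),
            "n_high": self.n_high.tolist(),
            "n_tests": self.n_tests,
            "hit_genes": {f"{i},{j}": idx.tolist() for (i, j), idx in self.hit_genes.items()},
        }
        with open(prefix.with_suffix(".meta.json"), "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, prefix) -> "ReLMatrix":
        prefix = Path(prefix)
        scores = pd.read_csv(prefix.with_suffix(".scores.tsv"), sep="\t", index_col=0)
        with open(prefix.with_suffix(".meta.json"), encoding="utf-8") as fh:
            m = json.load(fh)
        hit = {
            tuple(int(x) for x in key.split(",")): np.asarray(v, dtype=int)
            for key, v in m["hit_genes"].items()
        }
        return cls(
            marker_ids=m["marker_ids"],
            signature_ids=m["signature_ids"],
            gene_ids=m["gene_ids"],
            marker_chrom=m["marker_chrom"],
            marker_pos=np.asarray(m["marker_pos"], float),
            rel_score=scores.to_numpy(dtype=float),
            neg_log10_p=np.asarray(m["neg_log10_p"], float),
            direction=np.asarray(m["direction"], np.int8),
            threshold=np.asarray(m["threshold"], float),
            hypergeom_p=np.asarray(m["hypergeom_p"], float),
            n_high=np.asarray(m["n_high"], np.int32),
            hit_genes=hit,
            n_tests=int(m["n_tests"]),
        )


def compute_rel_matrix(
    linkage: LinkageMatrix,
    compendium: SignatureCompendium,
    marker_map: MarkerMap,
    min_shared_genes: int = MIN_SHARED_GENES,
) -> ReLMatrix:
    """Run the ReL test for every (marker, signature) pair.

    Genes are intersected between the linkage matrix and the compendium;
    markers are put in genomic order; the Bonferroni factor is the number of
    pairs in the run.
    """
    comp_genes = set(compendium.gene_ids)
    genes = [g for g in linkage.gene_ids if g in comp_genes]
    if len(genes) < min_shared_genes:
        raise ValueError(
            f"only {len(genes)} genes shared between linkage matrix and "
            f"compendium; need >= {min_shared_genes}"
        )
    dropped = (len(linkage.gene_ids) - len(genes)) + (len(compendium.gene_ids) - len(genes))
    if dropped:
        logger.info("relscore: dropped %d unshared gene ids", dropped)

    markers = marker_map.genomic_order(linkage.marker_ids)
    L = linkage.scores.loc[markers, genes].to_numpy(dtype=float)
    C = compendium.values.loc[genes].to_numpy(dtype=float)  # (G, S)
    sig_ids = compendium.signature_ids
    M, G = L.shape
    S = len(sig_ids)
    n_tests = bonferroni_factor(M, S)
    log_corr = math.log(n_tests)

    finite = np.isfinite(C)
    with np.errstate(invalid="ignore"):
        means = np.where(finite, C, 0.0).sum(axis=0) / np.maximum(finite.sum(axis=0), 1)
    over = finite & (C > means)    # (G, S)
    under = finite & (C < means)
    k_over = over.sum(axis=0)
    k_under = under.sum(axis=0)
    degenerate = np.array(
        [finite[:, j].sum() < 2 or len(np.unique(C[finite[:, j], j])) < 2 for j in range(S)]
    )
    if degenerate.any():
        logger.warning(
            "relscore: %d degenerate signatures scored 0: %s",
            degenerate.sum(), [sig_ids[j] for j in np.nonzero(degenerate)[0]][:5],
        )
    mem = np.concatenate([over, under], axis=1)  # (G, 2S)

    rel = np.zeros((M, S))
    direction = np.zeros((M, S), np.int8)
    thr = np.full((M, S), np.nan)
    n_high_arr = np.zeros((M, S), np.int32)
    hyp_k = np.zeros((M, S), np.int64)
    hyp_K = np.zeros((M, S), np.int64)
    hit_genes: dict = {}
    tstat = np.zeros((M, S))
    tdf = np.ones((M, S))
    small = np.zeros((M, S), bool)

    kk_all = np.concatenate([k_over, k_under]).astype(np.int64)  # (2S,)
    Cz = np.where(finite, C, 0.0)
    tot_n = finite.sum(axis=0).astype(float)
    tot_s = Cz.sum(axis=0)
    tot_q = (Cz * Cz).sum(axis=0)
    jj = np.arange(S)
    for i in range(M):
        s = L[i]
        order, ss, block_end, n_high = _sort_blocks(s)
        # one batched hypergeometric pass over all signatures and directions
        cs = np.cumsum(mem[order], axis=0)
        k_all = cs[block_end]  # (T, 2S)
        p_all = sf_batch(k_all, G, kk_all[None, :], n_high[:, None])
        p_all[:, np.concatenate([k_over == 0, k_under == 0])] = np.inf
        for j in range(S):
            if degenerate[j]:
                small[i, j] = True
                continue
            t, d, n_hi, k, _ = _choose_best(
                p_all[:, [j, S + j]], ss, block_end, n_high, k_all[:, [j, S + j]]
            )
            dsign = 1 if d == "up" else -1
            thr[i, j] = t
            direction[i, j] = dsign
            n_high_arr[i, j] = n_hi
            hyp_k[i, j] = k
            hyp_K[i, j] = k_over[j] if d == "up" else k_under[j]
            high = s >= t
            hit = high & (over[:, j] if dsign == 1 else under[:, j])
            hit_genes[(i, j)] = np.nonzero(hit)[0].astype(np.int32)
        # Welch t-test, all signatures at once: the high-linkage set is a
        # prefix of the sorted order, so group sums come from cumulative sums
        Csort = Cz[order]
        fsort = finite[order]
        cn = np.cumsum(fsort, axis=0).astype(float)
        csum = np.cumsum(Csort, axis=0)
        csq = np.cumsum(Csort * Csort, axis=0)
        row = n_high_arr[i] - 1
        n_a = cn[row, jj]
        s_a = csum[row, jj]
        q_a = csq[row, jj]
        n_b = tot_n - n_a
        with np.errstate(divide="ignore", invalid="ignore"):
            m_a = s_a / n_a
            m_b = (tot_s - s_a) / n_b
            v_a = np.maximum(q_a - n_a * m_a**2, 0.0) / (n_a - 1)
            v_b = np.maximum((tot_q - q_a) - n_b * m_b**2, 0.0) / (n_b - 1)
            se2_a = v_a / n_a
            se2_b = v_b / n_b
            se2 = se2_a + se2_b
            tval = np.abs(m_a - m_b) / np.sqrt(se2)
            df = se2**2 / (se2_a**2 / (n_a - 1) + se2_b**2 / (n_b - 1))
        bad = (n_a < 2) | (n_b < 2) | ~np.isfinite(tval) | ~np.isfinite(df)
        small[i] |= bad
        ok_j = ~small[i]
        tstat[i, ok_j] = tval[ok_j]
        tdf[i, ok_j] = df[ok_j]

    ok = ~small
    nlp = np.zeros((M, S))
    logp = math.log(2.0) + stats.t.logsf(tstat[ok], tdf[ok])
    nlp[ok] = -logp / _LN10
    rel[ok] = np.maximum(0.0, -(logp + log_corr) / _LN10)
    hyp = np.ones((M, S))
    hyp.ravel()[np.flatnonzero(direction)] = stats.hypergeom.sf(
        hyp_k.ravel()[np.flatnonzero(direction)] - 1,
        G,
        hyp_K.ravel()[np.flatnonzero(direction)],
        n_high_arr.ravel()[np.flatnonzero(direction)],
    )
    n_sig = int((rel > 0).sum())
    logger.info(
        "relscore: %d x %d = %d entries, %d with positive corrected score",
        M, S, M * S, n_sig,
    )
    return ReLMatrix(
        marker_ids=markers,
        signature_ids=list(sig_ids),
        gene_ids=genes,
        marker_chrom=[marker_map.chromosome(m) for m in markers],
        marker_pos=np.array([marker_map.position_kb(m) for m in markers]),
        rel_score=rel,
        neg_log10_p=nlp,
        direction=direction,
        threshold=thr,
        hypergeom_p=hyp,
        n_high=n_high_arr,
        hit_genes=hit_genes,
        n_tests=n_tests,
    )
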