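"""Contiguity-constrained iterative signature algorithm (ISA) on the ReL matrix.

A ReL module is a contiguous interval of genetic markers on one chromosome
plus a set of regulatory signatures whose sub-matrix of ReL scores is
coherently high.  Starting from single high-scoring entries, the algorithm
alternates two refinements until a fixed point:

* signature update — keep signatures whose mean ReL score over the current
  interval is >= tau_col;
* interval update — over the markers of the current chromosome, with the
  per-marker gain g(m) = mean ReL score over the current signatures, find the
  contiguous interval maximizing sum(g(m) - tau_row) (a maximum-subarray
  problem, solved exactly).

The iteration is deterministic; a state revisited without being a fixed
point is an oscillation and yields no module.  Converged modules below the
reporting score floor or the minimum size are discarded; near-duplicate
attractors from different seeds are merged by Jaccard similarity of their
entry sets.  Module significance is assessed by re-running the search on
matrices with scores permuted within each signature column, which preserves
per-signature score distributions while destroying marker structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .relscore import ReLMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ISAParams:
    tau_row: float = 3.0
    tau_col: float = 3.0
    max_iter: int = 50
    min_signatures: int = 1
    min_markers: int = 1
    score_floor: float = 3.0

    def __post_init__(self):
        if self.tau_row < 0 or self.tau_col < 0:
            raise ValueError("thresholds must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ReLModule:
    """A contiguous marker interval x signature set with its mean ReL score."""

    chromosome: str
    start: int                      # index into the ReL matrix marker order
    end: int                        # inclusive
    marker_ids: tuple[str, ...]
    signatures: tuple[str, ...]
    signature_idx: tuple[int, ...]
    module_score: float
    start_kb: float = float("nan")
    end_kb: float = float("nan")
    seed: tuple[int, int] | None = None
    n_iter: int = 0

    @property
    def n_markers(self) -> int:
        return self.end - self.start + 1

    @property
    def area(self) -> int:
        return self.n_markers * len(self.signatures)

    def entry_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            (m, j) for m in range(self.start, self.end + 1) for j in self.signature_idx
        )


def update_signatures(scores: np.ndarray, interval: tuple[int, int], tau_col: float) -> np.ndarray:
    """Indices of signatures whose mean score over the interval is >= tau_col."""
    lo, hi = interval
    g = scores[lo : hi + 1].mean(axis=0)
    return np.nonzero(g >= tau_col)[0]


def optimize_interval(
    scores: np.ndarray,
    signature_idx,
    chrom_slice: slice,
    tau_row: float,
) -> tuple[int, int] | None:
    """Best contiguous marker interval within one chromosome.

    Maximizes sum over the interval of (g(m) - tau_row), g(m) being the mean
    score over the given signatures.  Returns global (start, end) inclusive,
    or None when every interval has negative gain (all g(m) < tau_row).
    Ties resolve to the lexicographically smallest (start, end).
    """
    sig = np.asarray(signature_idx, dtype=int)
    if sig.size == 0:
        return None
    g = scores[chrom_slice, :][:, sig].mean(axis=1) - tau_row
    m = g.shape[0]
    best_gain = -np.inf
    best = None
    # per-start cumulative sums: O(m^2) work but vectorized per start; the
    # same summation is reused to locate the argmax, so ties are resolved
    # identically on every call (smallest start, then smallest end)
    for s in range(m):
        c = np.cumsum(g[s:])
        e_rel = int(np.argmax(c))
        if c[e_rel] > best_gain:
            best_gain = float(c[e_rel])
            best = (s, s + e_rel)
    if best is None or best_gain < 0.0:
        return None
    off = chrom_slice.start
    return (off + best[0], off + best[1])


def chromosome_slices(marker_chrom) -> dict[str, slice]:
    """Contiguous marker-index slice per chromosome (markers in genomic order)."""
    out: dict[str, slice] = {}
    start = 0
    for i in range(1, len(marker_chrom) + 1):
        if i == len(marker_chrom) or marker_chrom[i] != marker_chrom[start]:
            c = marker_chrom[start]
            if c in out:
                raise ValueError(f"markers of chromosome {c!r} are not contiguous")
            out[c] = slice(start, i)
            start = i
    return out


def _run_isa_scores(
    scores: np.ndarray,
    marker_chrom,
    seed_entry: tuple[int, int],
    params: ISAParams,
    chrom_slices: dict[str, slice] | None = None,
):
    """ISA iteration on a raw score matrix; returns (interval, sig_idx, n_iter)
    on convergence, else None."""
    if chrom_slices is None:
        chrom_slices = chromosome_slices(marker_chrom)
    mi, _ = seed_entry
    cslice = chrom_slices[marker_chrom[mi]]
    interval = (mi, mi)
    prev = None
    seen = set()
    for it in range(1, params.max_iter + 1):
        sig = update_signatures(scores, interval, params.tau_col)
        if sig.size == 0:
            return None
        new_interval = optimize_interval(scores, sig, cslice, params.tau_row)
        if new_interval is None:
            return None
        state = (new_interval, tuple(sig))
        if state == prev:
            return new_interval, sig, it
        if state in seen:
            logger.debug("ISA oscillation from seed %s", seed_entry)
            return None
        seen.add(state)
        prev = state
        interval = new_interval
    return None


def _module_from_state(rel: ReLMatrix, interval, sig_idx, seed, n_iter, params):
    lo, hi = interval
    sig_idx = tuple(int(j) for j in sig_idx)
    score = float(rel.rel_score[lo : hi + 1, list(sig_idx)].mean())
    if score < params.score_floor:
        return None
    if (hi - lo + 1) < params.min_markers or len(sig_idx) < params.min_signatures:
        return None
    return ReLModule(
        chromosome=rel.marker_chrom[lo],
        start=lo,
        end=hi,
        marker_ids=tuple(rel.marker_ids[lo : hi + 1]),
        signatures=tuple(rel.signature_ids[j] for j in sig_idx),
        signature_idx=sig_idx,
        module_score=score,
        start_kb=float(rel.marker_pos[lo]),
        end_kb=float(rel.marker_pos[hi]),
        seed=seed,
        n_iter=n_iter,
    )


def run_isa(rel: ReLMatrix, seed_entry: tuple[int, int], params: ISAParams) -> ReLModule | None:
    """Optimize one seed entry to a fixed point; None if it does not converge
    to a reportable module."""
    res = _run_isa_scores(rel.rel_score, rel.marker_chrom, seed_entry, params)
    if res is None:
        return None
    interval, sig, n_iter = res
    return _module_from_state(rel, interval, sig, seed_entry, n_iter, params)


def seed_entries(rel: ReLMatrix, min_seed_score: float = 3.0) -> list[tuple[int, int]]:
    """All entries with rel_score >= min_seed_score, highest score first."""
    flat = rel.rel_score.ravel()
    idx = np.flatnonzero(flat >= min_seed_score)
    idx = idx[np.argsort(-flat[idx], kind="stable")]
    S = rel.rel_score.shape[1]
    return [(int(i // S), int(i % S)) for i in idx]


def deduplicate(modules: list[ReLModule], jaccard_cutoff: float = 0.5) -> list[ReLModule]:
    """Merge modules whose entry sets overlap (transitively) at Jaccard >=
    cutoff, keeping the highest-scoring representative of each group."""
    n = len(modules)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sets = [m.entry_set() for m in modules]
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if inter == 0:
                continue
            union = len(sets[i]) + len(sets[j]) - inter
            if inter / union >= jaccard_cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    reps = []
    for members in groups.values():
        reps.append(max(members, key=lambda i: (modules[i].module_score, -i)))
    out = [modules[i] for i in reps]
    out.sort(key=lambda m: -m.module_score)
    return out


def find_modules(
    rel: ReLMatrix,
    params: ISAParams = ISAParams(),
    min_seed_score: float | None = 3.0,
    jaccard_cutoff: float = 0.5,
) -> list[ReLModule]:
    """Seed, optimize, and deduplicate: the full module search.

    ``min_seed_score=None`` seeds from every entry of the matrix (the
    exhaustive rule); the default restricts seeds to significant entries,
    which reach the same attractors.
    """
    seeds = seed_entries(rel, 0.0 if min_seed_score is None else min_seed_score)
    raw = []
    seen_states = set()
    for seed in seeds:
        mod = run_isa(rel, seed, params)
        if mod is None:
            continue
        key = (mod.start, mod.end, mod.signature_idx)
        if key in seen_states:
            continue
        seen_states.add(key)
        raw.append(mod)
    logger.info("biclust: %d seeds -> %d distinct converged modules", len(seeds), len(raw))
    out = deduplicate(raw, jaccard_cutoff)
    logger.info("biclust: %d modules after deduplication", len(out))
    return out


def module_size_pvalue(
    module: ReLModule,
    rel: ReLMatrix,
    n_perm: int,
    rng_seed: int,
    params: ISAParams = ISAParams(),
    shuffle: bool = True,
) -> float:
    """Permutation P-value for the module's (area x score) statistic.

    Each null draw shuffles the ReL scores independently within every
    signature column, seeds ISA at the best entry of the permuted matrix, and
    records the resulting area x score (0 when no module converges).
    P = (1 + #null >= observed) / (1 + n_perm).  ``shuffle=False`` evaluates
    the unpermuted matrix as the null draw (a degenerate self-test giving
    P = 1 when the module is the matrix's own best attractor).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng_seed)
    observed = module.area * module.module_score
    cslices = chromosome_slices(rel.marker_chrom)
    exceed = 0
    for _ in range(n_perm):
        if shuffle:
            perm = rng.permuted(rel.rel_score, axis=0)
        else:
            perm = rel.rel_score
        best_flat = int(np.argmax(perm))
        seed = (best_flat // perm.shape[1], best_flat % perm.shape[1])
        res = _run_isa_scores(perm, rel.marker_chrom, seed, params, cslices)
        stat = 0.0
        if res is not None:
            (lo, hi), sig, _ = res
            sub = perm[lo : hi + 1][:, sig]
            score = float(sub.mean())
            if score >= params.score_floor and (hi - lo + 1) >= params.min_markers \
                    and len(sig) >= params.min_signatures:
                stat = sub.size * score
        if stat >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
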