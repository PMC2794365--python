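"""eQTL likelihood (regression LOD) linkage between markers and expression.

The linkage statistic for one (marker, gene) pair is the two-class regression
LOD for a haploid cross:

    LOD = (n / 2) * log10(RSS0 / RSS1)

where RSS0 is the residual sum of squares about the grand expression mean,
RSS1 about the per-allele-class means, and n the number of segregants with
both a genotype call and an expression value.  The statistic is monotone in
the two-sample t statistic and non-negative; degenerate perfect fits
(RSS1 = 0 with RSS0 > 0) are capped at LOD_CAP.  Pairs with fewer than
MIN_CLASS_SIZE informative segregants in either allele class are scored as
missing (NaN) and set to 0 (with a logged count) when assembling the full
matrix, so downstream threshold scans see a complete, finite matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

LOD_CAP = 50.0
MIN_CLASS_SIZE = 3
MIN_SHARED_SEGREGANTS = 20
_RSS_TOL = 1e-12


@dataclass
class LinkageMatrix:
    """markers x genes matrix of eQTL likelihood (LOD) scores, all >= 0."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.scores.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or (v < 0).any():
            raise ValueError("linkage scores must be finite and >= 0")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.columns)


def _lod_from_rss(rss0: np.ndarray, rss1: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized LOD with the degenerate-fit conventions."""
    rss0 = np.maximum(rss0, 0.0)
    rss1 = np.maximum(rss1, 0.0)
    scale = np.maximum(rss0, 1.0)
    no_signal = rss0 <= _RSS_TOL * scale  # constant expression: no variance at all
    perfect = (rss1 <= _RSS_TOL * scale) & ~no_signal
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(rss0 / np.maximum(rss1, 1e-300))
    lod = np.where(no_signal, 0.0, lod)
    lod = np.where(perfect, LOD_CAP, lod)
    return np.minimum(np.maximum(lod, 0.0), LOD_CAP)


def eqtl_likelihood(genotype_calls, expression) -> float:
    """Regression LOD for one marker / one gene; NaN if either allele class
    has fewer than MIN_CLASS_SIZE informative segregants."""
    a = np.asarray(genotype_calls, dtype=float)
    x = np.asarray(expression, dtype=float)
    if a.shape != x.shape:
        raise ValueError("genotype and expression vectors must align by segregant")
    ok = ~np.isnan(a) & ~np.isnan(x)
    a, x = a[ok], x[ok]
    n0 = int(np.sum(a == 0))
    n1 = int(np.sum(a == 1))
    if n0 < MIN_CLASS_SIZE or n1 < MIN_CLASS_SIZE:
        return float("nan")
    n = n0 + n1
    rss0 = float(np.sum((x - x.mean()) ** 2))
    m0 = x[a == 0].mean()
    m1 = x[a == 1].mean()
    rss1 = float(np.sum((x[a == 0] - m0) ** 2) + np.sum((x[a == 1] - m1) ** 2))
    return float(_lod_from_rss(np.array(rss0), np.array(rss1), np.array(float(n))))


def _marker_lods(allele: np.ndarray, expr: np.ndarray) -> np.ndarray:
    """LOD of one marker against every gene (rows of ``expr``), with pairwise
    deletion of missing entries.  Returns NaN where a class is too small."""
    finite = np.isfinite(expr)
    w0 = (allele == 0.0)
    w1 = (allele == 1.0)
    x = np.where(finite, expr, 0.0)
    x2 = x * x
    n0 = finite[:, w0].sum(axis=1)
    n1 = finite[:, w1].sum(axis=1)
    s0 = x[:, w0].sum(axis=1)
    s1 = x[:, w1].sum(axis=1)
    q0 = x2[:, w0].sum(axis=1)
    q1 = x2[:, w1].sum(axis=1)
    n = n0 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s0 / n0
        m1 = s1 / n1
        grand = (s0 + s1) / n
        rss0 = (q0 + q1) - n * grand**2
        rss1 = (q0 - n0 * m0**2) + (q1 - n1 * m1**2)
    lod = _lod_from_rss(rss0, rss1, n.astype(float))
    lod[(n0 < MIN_CLASS_SIZE) | (n1 < MIN_CLASS_SIZE)] = np.nan
    return lod


def compute_linkage_matrix(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    min_shared_segregants: int = MIN_SHARED_SEGREGANTS,
) -> LinkageMatrix:
    """Score every (marker, gene) pair; missing scores become 0 (logged)."""
    shared = [s for s in genotypes.segregant_ids if s in set(expression.sample_ids)]
    if not shared:
        raise ValueError("genotype and expression matrices share no segregants")
    if len(shared) < min_shared_segregants:
        raise ValueError(
            f"only {len(shared)} shared segregants; need >= {min_shared_segregants}"
        )
    dropped = (len(genotypes.segregant_ids) - len(shared)) + (
        len(expression.sample_ids) - len(shared)
    )
    if dropped:
        logger.info("linkage: dropped %d unshared segregant columns", dropped)
    calls = genotypes.calls[shared].to_numpy(dtype=float)
    expr = expression.values[shared].to_numpy(dtype=float)
    out = np.empty((calls.shape[0], expr.shape[0]))
    for i in range(calls.shape[0]):
        out[i] = _marker_lods(calls[i], expr)
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.info("linkage: %d (marker, gene) scores missing, set to 0", n_missing)
        out = np.nan_to_num(out, nan=0.0)
    return LinkageMatrix(
        scores=pd.DataFrame(out, index=genotypes.marker_ids, columns=expression.gene_ids)
    )


def _rsquared_rows(allele: np.ndarray, expr: np.ndarray) -> np.ndarray:
    """Per-gene R^2 of the allele-class-mean model; zero-variance genes get 0."""
    ok = ~np.isnan(allele)
    a = allele[ok]
    x = expr[:, ok]
    finite = np.isfinite(x)
    xv = np.where(finite, x, 0.0)
    r2 = np.zeros(expr.shape[0])
    w0 = (a == 0.0)
    w1 = (a == 1.0)
    n0 = finite[:, w0].sum(axis=1)
    n1 = finite[:, w1].sum(axis=1)
    n = n0 + n1
    s0 = xv[:, w0].sum(axis=1)
    s1 = xv[:, w1].sum(axis=1)
    q = (xv * xv * finite).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        grand = (s0 + s1) / n
        rss0 = q - n * grand**2
        rss1 = (q - (s0**2 / np.maximum(n0, 1)) - (s1**2 / np.maximum(n1, 1)))
    good = (rss0 > _RSS_TOL * np.maximum(rss0, 1.0)) & (n0 > 0) & (n1 > 0)
    r2[good] = 1.0 - np.maximum(rss1[good], 0.0) / rss0[good]
    return np.clip(r2, 0.0, 1.0)


def variance_explained(genotype_calls, expression_rows) -> float:
    """Mean per-gene R^2 of the single-locus allele-class-mean model over a
    gene set.  ``expression_rows`` is genes x segregants, aligned with the
    call vector."""
    a = np.asarray(genotype_calls, dtype=float)
    x = np.atleast_2d(np.asarray(expression_rows, dtype=float))
    if x.shape[1] != a.shape[0]:
        raise ValueError("expression rows must align with the genotype vector")
    if x.shape[0] < 1:
        raise ValueError("need at least one gene")
    return float(_rsquared_rows(a, x).mean())


def two_locus_summary(calls_A, calls_B, expression_rows) -> dict:
    """Four-genotype-class expression means and joint R^2 for a marker pair.

    Class means average over genes first, then over segregants within each
    (allele_A, allele_B) class; empty classes are reported as NaN.  The joint
    R^2 is the mean over genes of the four-class-mean model R^2, computed
    over segregants in non-empty classes.
    """
    a = np.asarray(calls_A, dtype=float)
    b = np.asarray(calls_B, dtype=float)
    x = np.atleast_2d(np.asarray(expression_rows, dtype=float))
    if a.shape != b.shape or x.shape[1] != a.shape[0]:
        raise ValueError("inputs must align by segregant")
    ok = ~np.isnan(a) & ~np.isnan(b)
    per_seg = np.nanmean(x, axis=0)
    class_means: dict[tuple[int, int], float] = {}
    for ga in (0, 1):
        for gb in (0, 1):
            sel = ok & (a == ga) & (b == gb)
            class_means[(ga, gb)] = float(np.nanmean(per_seg[sel])) if sel.any() else float("nan")
    # joint model: one mean per populated genotype class, per gene
    combo = np.where(ok, 2 * a + b, np.nan)
    r2s = np.zeros(x.shape[0])
    for gi in range(x.shape[0]):
        row = x[gi]
        sel = ok & np.isfinite(row)
        if sel.sum() < 2:
            continue
        y = row[sel]
        c = combo[sel]
        rss0 = float(np.sum((y - y.mean()) ** 2))
        if rss0 <= _RSS_TOL * max(rss0, 1.0):
            continue
        rss1 = 0.0
        for cls in np.unique(c):
            yy = y[c == cls]
            rss1 += float(np.sum((yy - yy.mean()) ** 2))
        r2s[gi] = min(max(1.0 - rss1 / rss0, 0.0), 1.0)
    return {"class_means": class_means, "joint_r2": float(r2s.mean())}
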