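# Methods

## Model and procedure

`relmod` assumes a haploid segregating population from a two-parent cross:
genotypes are biallelic (0 = parent A, 1 = parent B) with no heterozygotes,
and expression values are log ratios. Two inputs carry the biology: a
genotype/expression pair over shared segregants, and a compendium of
regulatory signatures — genome-wide log2 mutant/wild-type profiles, one per
single-gene regulatory mutant, each mapped to its mutated protein (several
profiles may map to one protein).

The analysis proceeds in four stages.

1. **Linkage.** Every (marker, gene) pair is scored with the two-class
   regression LOD, `(n/2)·log10(RSS0/RSS1)`. The LOD is non-negative and
   monotone in the two-sample t statistic; downstream steps consume only the
   ordering of scores within a marker column, so any monotone-equivalent
   linkage statistic yields the same modules with shifted thresholds.
2. **ReL test.** Per (marker, signature): the signature splits genes at its
   mean into over-/under-expressed groups (genes exactly at the mean, or
   with missing values, join neither). Every observed linkage value is a
   candidate inclusive threshold; the (threshold, direction) pair minimizing
   the hypergeometric upper-tail P of |high-linkage ∩ group| is selected
   (ties: smaller threshold, then "up"). Welch's t-test then compares
   signature values of high-linkage genes against all remaining scored
   genes; the ReL score is −log10 of the Bonferroni-corrected two-sided P,
   floored at 0, with the correction factor equal to the number of
   marker × signature pairs in the run.
3. **Biclustering.** Contiguity-constrained ISA: from each significant entry
   as seed, alternate a signature update (keep signatures with interval-mean
   score ≥ τ_col) and an exact maximum-subarray re-optimization of the
   contiguous marker interval on the seed's chromosome (gain
   Σ(g(m) − τ_row), g(m) = mean score over current signatures). Iteration is
   deterministic; convergence is an exact state repeat, detected by state
   hashing, and a revisited non-fixed state (limit cycle) discards the seed.
   Converged modules below the score floor or size minima are dropped;
   attractor duplicates are merged transitively at entry-set Jaccard ≥ 0.5,
   keeping the highest-scoring representative.
4. **Annotation.** Target genes are hit genes present in ≥ 60% of the
   module's entries minus cis genes; protein scores average each protein's
   signature-interval means; enrichment and causal-candidate ranking use
   hypergeometric tests with Bonferroni correction (Benjamini–Hochberg
   selectable).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `tau_row`, `tau_col` | 3.0 | ISA inclusion thresholds on the ReL score (−log10 corrected P); aligned with the module reporting floor |
| `score_floor` | 3.0 | minimum mean ReL score of a reported module (corrected P < 10⁻³) |
| `min_seed_score` | 3.0 | seed entries restricted to significant scores; `None`/`--seed-all` restores seeding from every entry (identical attractors, much slower) |
| `jaccard_cutoff` | 0.5 | entry-set similarity at which two converged modules are considered one attractor |
| `max_iter` | 50 | ISA iteration cap; typical convergence is < 10 rounds |
| `frac` | 0.6 | fraction of module entries in which a hit gene must appear to become a target |
| `cis_gene_window` | 30 | genes-away distance (gene-order index, not kb) below which a target is considered cis and excluded |
| `telomere_kb`, `min_frac`, `min_chroms` | 30 kb, 0.5, 3 | telomere-flag rule; this flag was a manual curation step in the source analyses, so the defaults are this package's own operationalization |
| `n_perm` | off (100 recommended) | within-column score permutations for the module size P-value |
| LOD cap | 50 | score assigned to degenerate perfect fits (RSS1 = 0), keeping the threshold scan finite and totally ordered |

Missing data: genotype/expression pairs are deleted pairwise per (marker,
gene); (marker, gene) scores with an allele class of < 3 informative
segregants, and degenerate (constant) signatures, score 0 with a logged
count, so biclustering always sees a complete finite matrix.

## Numerical choices

- The threshold scan needs tens of millions of hypergeometric tails per
  dataset; they are computed by a numba-compiled exact tail sum (lgamma
  starting term, multiplicative pmf recurrence, summation on the shorter
  side of the mode). Reported per-entry P-values are recomputed with
  scipy.stats.hypergeom, and tests compare the scan against a scipy
  brute-force oracle.
- ReL scores are computed from the log survival function of the t
  distribution, so strongly separated groups yield large finite scores
  instead of underflowing to infinity.
- Interval optimization resolves ties to the lexicographically smallest
  (start, end); interval sums are accumulated per start so the same
  arithmetic locates the optimum on every call.
- Intervals are confined to a single chromosome (an assumption: every
  reported interval in the source analyses was single-chromosome).
- The ISA thresholds are absolute values on the −log10 corrected P scale
  rather than standard-deviation units; the original biclustering's exact
  normalization scheme is not reproduced.

## What the simulator emulates — and what it does not

`simulate` reproduces the statistical structure the method relies on:
Mendelian 0/1 genotypes with uniform Markov recombination along
chromosomes (adjacent-marker switch probability `r`), trans-linked gene
groups whose expression shifts by β with the causal allele against Gaussian
noise, and mutant signatures in which the same genes shift by δ against
Gaussian background. Default study conditions: 112 segregants, three 500 kb
chromosomes × 100 markers, r = 0.1, 1000 genes, 40 signatures, three planted
modules of 40 member genes with β = 1 (σ_e = 0.5, i.e. single-locus
R² ≈ 0.5) and δ = 2 (σ_sig = 0.3). Member genes are placed on chromosomes
other than their causal marker so cis exclusion never removes true targets.

Not emulated: realistic linkage-disequilibrium structure and genetic-map
distortion, hotspot interference, batch or growth-condition effects,
correlated noise between signatures, partially overlapping regulons, or
missing data patterns. Passing recovery tests therefore show the algorithm
recovers well-separated planted structure at realistic effect sizes; they do
not bound performance on real crosses, where signature redundancy and LD
make interval boundaries and signature sets fuzzier.

## Calibration of the ReL P-value

The raw (uncorrected) t-test P is *not* calibrated under the null, by
construction: the threshold scan picks, per entry, the high-linkage split
most over-represented in the signature's over/under group, and the t-test is
run on that optimized split. On structureless simulations the fraction of
entries with uncorrected P < 0.001 is ~0.03 (computed by
`scripts/acceptance.py` as `null_frac_uncorrected_p_below_0.001`), an
order of magnitude above nominal. The method's operative guards are the
Bonferroni correction, the module score floor, and the permutation size
test, which re-runs the full search on within-column-shuffled matrices and
therefore inherits the same selection effect in its null draws: on the same
structureless simulations, modules that clear the score floor do not survive
the permutation test. ReL scores should be read as a ranking statistic with
a permutation-calibrated module-level P, not as calibrated per-entry
P-values.

## Known limitations

- Single-interval modules only; epistatic (multi-locus) modules are outside
  the search space — the two-locus summary in `linkage` supports manual
  analysis of candidate pairs.
- Bonferroni (not FDR) is the only correction for ReL scores in v1.
- The hypergeometric scan searches both directions over the two expression
  groups; whether to also search both tails within one group is an open
  design point, resolved here as "no".
- The t-test "rest" group is all scored genes outside the high-linkage set,
  including genes at the signature mean.
- With `min_seed_score` > 0 the seed set is a subset of the exhaustive rule;
  on all tested fixtures the attractor set is unchanged, but a module whose
  every entry is individually non-significant would be reachable only via
  `--seed-all`.
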