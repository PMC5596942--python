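# Methods notes

This note records the modelling choices behind each stage, the defaults and
why they were chosen, what the synthetic benchmark does and does not show,
and the numerical conventions that make runs reproducible.

## Differential expression

**SAM statistic.** For gene *i*, d_i = r_i/(s_i + s0) with r_i the
disease−control mean difference and s_i the pooled standard error
√((1/n₁+1/n₂)·SS/(n₁+n₂−2)). The original method leaves several details
open; ours are:

- **s0 grid**: percentiles 0, 5, …, 100 of the s_i distribution. For each
  candidate we bin genes into `max(1, min(100, n_genes//3))` s-quantile
  bins, compute the MAD (scaled by 1/0.6745) of d within each bin, and
  minimise the coefficient of variation of those MADs. Ties take the
  smallest s0. With very few genes the binning degrades gracefully to one
  bin, where every candidate ties and the smallest s0 wins — deterministic
  by construction.
- **Permutation null**: all C(n₁+n₂, n₂) group relabellings when that count
  is ≤ `n_permutations` (default 200), otherwise that many distinct
  relabellings drawn uniformly without replacement from the seeded
  generator. Exhaustive instances therefore need no seed.
- **Calling band**: observed d are sorted against the permutation-mean
  order statistics d̄; for a band δ the upper cutoff is the smallest
  positive sorted d with d−d̄ ≥ δ (lower cutoff symmetric) and genes beyond
  a cutoff are called. This makes the called set monotone non-increasing
  in δ.
- **FDR**: π0 × median over permutations of the null count beyond the
  cutoffs, divided by the observed call count; π0 is the fraction of
  observed d inside the central 50% of the pooled permuted d, capped at 1.
  No calls ⇒ FDR 0. δ is the smallest candidate (unique |d−d̄| values)
  meeting the target, so the selection always terminates.
- **Degenerate genes**: a zero-variance gene with s0 = 0 would give 0/0;
  d is defined as 0 there and the condition is logged.

**t-test.** The unequal-variance (Welch) statistic with
Welch–Satterthwaite degrees of freedom, two-sided p. Zero variance in both
groups with equal means gives t = 0, p = 1 by convention (logged); with
different means, p = 0. The direction convention matches SAM
(disease − control).

**Fold change** is reported on the linear scale: 2^(mean difference) for
log2 matrices (the default — GCRMA-style normalisation emits log2),
a plain ratio for linear matrices, with zero control means flagged as NaN
rather than raised. Values below 1 denote down-regulation in disease.

**Tail strength** follows the order-statistic definition
(1/m)Σ_k(1 − p_(k)(m+1)/k); it is 0 in expectation under the uniform null
and approaches 1 as the p-values collapse to 0.

## Co-expression network

Unsigned adjacency |cor|^β (Pearson by default, Spearman by flag): the
sign-free form is the long-standing default for this workflow and keeps
the planted-factor benchmark interpretable. β is the smallest candidate
whose scale-free fit R² (log₁₀ frequency vs log₁₀ mean connectivity over
10 equal-width bins, sign-corrected so rising fits score ≤ 0) reaches the
target, falling back to the R²-maximising candidate with a warning. The
sign-corrected index is clamped at 0 for the target comparison so a target
of 0 trivially returns the smallest candidate.

TOM uses the standard shared-neighbour normalisation; the diagonal is 1 by
convention and isolated pairs give 0.

**Module detection** is average-linkage clustering of 1−TOM with a
*static* cut (dynamic tree cutting is deliberately out of scope). The
default cut height is **0.95 on the 1−TOM scale**: factor-driven module
merges sit far below it while merges involving uncorrelated background
concentrate near 1. We evaluated a cut placed relative to the maximum
merge height (0.995·max) and found it unusable — background merges also
approach the maximum, so the cut lands above the module/background
separation and fuses everything; the absolute 0.95 cut recovers planted
modules exactly at the default sample sizes. Clusters below
`min_module_size` (default 25, a typical smallest reported module size in
co-expression analyses of this scale) are set to grey. Colours follow the canonical
size-ordered palette, ties broken by first gene position, so "turquoise =
largest" is deterministic.

**ORA** is a one-sided hypergeometric test per gene set with BH correction
across sets; gene sets are intersected with the universe first.

## Module topology and hubs

The module graph uses an explicit |cor| ≥ threshold rule (default 0.5),
recorded in the graph metadata, since co-expression weights must be
binarised somehow before path-based centralities are meaningful.
Betweenness is exact and unnormalised (Brandes, via networkx);
disconnected pairs contribute nothing. HC hubs are the top
`round(hc_fraction·n)` by degree with the tie-break (degree desc, bc desc,
id asc) fixed so the set size is exact; HBLC hubs require
bc > mean + z·sd (z = 2 by default, population sd so a constant bc vector
yields none) *and* degree below the `low_degree_quantile` (default
median), HC excluded. The z/quantile quantification is ours: the hub
classes are usually named qualitatively, without canonical thresholds.

## Regulatory networks

Curated edge tables are the interface; no live database clients. miRNA
identifiers are matched case-insensitively (arm suffixes -5p/-3p stay
distinct); TF and gene symbols are matched verbatim. Assembly keeps
miRNA→gene edges targeting the module, then attaches TFs with at least one
edge onto an included miRNA or gene; a node can carry several roles (a
module gene that is also a TF). FFL enumeration covers exactly the
composite TF→miRNA→gene ∧ TF→gene loop; modes are carried through but do
not filter motifs. The sponge-network filter keeps lncRNA–miRNA pairs that
are validated **or** predicted with score ≥ 0.70 (the disjunctive reading;
`LncNetFilter(require_validated=True)` gives the conjunctive one), then
attaches mTFs and targets of the retained miRNAs.

## SNP screen

Boundary semantics are fixed as: p ≤ max_p (inclusive, default 1e−5),
frequency > min_freq (strict, default 0.10). Population labels are data,
not filters; a SNP associated with several miRNAs or populations
contributes several rows, and distinct-id counts are always reported
alongside row counts. Malformed rs ids drop the row with a logged warning;
SNPs missing from the functional table are kept as "unannotated".

## Synthetic data

The generator emulates a two-group log2 microarray study. Defaults mirror
the scale of the motivating data: 458 genes, 18 control / 29 disease
samples, module sizes 266/56/43/42/25/25, factor loading 0.85, residual
sd 0.3, 30% DE genes shifted by 2 residual-sd units. Choices:

- **Single latent factor per module** with gene value
  loading·f_m + noise_sd·ε around a uniform(6,10) baseline. This gives the
  closed-form expected within-module correlation
  loading²/(loading²+noise²), which the tests verify empirically.
- **DE as additive shifts** on the disease columns (log-scale microarray
  convention).
- **Exact planted FFL counts** via disjoint planted triples plus rejection
  sampling of every other random edge (an edge closing any new loop is
  re-drawn). Exactness of the planted count is the only guarantee; edge
  densities are otherwise arbitrary.
- **Exact SNP survivor sets**: each non-survivor is assigned one explicit
  failure mode (p too large, frequency too low, off-module gene, no
  binding record, non-3′UTR binding, non-disease miRNA — the last only
  when a non-disease miRNA exists).
- All randomness flows from `seed` through per-table generator streams;
  identical configs give byte-identical outputs.

What the benchmark does **not** emulate: probe-level effects, batch
structure, heteroscedastic noise, correlated DE/module membership beyond
chance, non-Gaussian intensity distributions, and realistic biological
edge densities. Passing the recovery suites therefore demonstrates
algorithmic correctness (the stages recover exactly what was planted under
their stated assumptions), not performance on real arrays. The noise model
is a convention, not a claim about any particular dataset.

## Problem sizes in tests

The oracle suites run at sizes where exhaustive computation is exact and
fast: SAM against a plain-loop reimplementation on ≤ 8-sample instances
(exhaustive permutations, agreement to 1e−10); betweenness against a BFS
path-counting oracle on graphs up to 40 nodes; FFL enumeration against an
O(n³) scan; module recovery averaged over 10 seeds at 120 genes; the null
FDR check over 20 seeds at 300 genes. These sizes were chosen so every
oracle remains exact while the whole suite stays interactive.

## Known limitations

- Static tree cut only; fragmented or nested modules that need dynamic
  cutting will under-split.
- No module eigengenes or module–trait statistics.
- SAM is two-class unpaired only; no moderated-variance (eBayes-style)
  alternative.
- The scale-free β selection is unstable on strongly blocky (non
  scale-free) correlation structure and then falls back with a warning;
  pass `beta` explicitly in that regime.
- Probe-to-gene collapsing, normalisation and batch correction are
  upstream of this package.
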