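# Methods

## Overview

`crequtl` maps *co-regulatory* expression quantitative trait loci: genetic
variants associated not with the expression level of a single transcript
but with how tightly a whole cluster of co-expressed genes moves together
in each sample.  The pipeline has three stages: (1) discover co-regulated
gene clusters from expression data alone, with a rank-based biclustering
heuristic; (2) score every sample's cluster tightness with a moderated
statistic; (3) test, genome-wide, whether the *variance* of that tightness
differs across SNP genotype classes.

## Rank normalization

Expression values are replaced per gene by their ranks r ∈ {1..p}
(mid-ranks for ties), mapped onto the symmetric equally spaced grid
a·(2(r−1)/(p−1) − 1) with a = √((p−1)/(p+1)).  For a gene with p distinct
values this gives mean exactly 0 and population variance exactly 1/3; the
tests assert both to 1e−9.  The map is monotone within each gene, so the
whole pipeline is invariant to any strictly increasing per-gene transform
of the input.  A gene constant across all samples maps to a zero row
(with a warning) rather than erroring, keeping matrix shapes stable.

## Per-sample tightness: Z_E and Z2_E

For a query set Q of k genes, sample j's tightness is

    Z_E(j) = √k · Ȳ_Q,j / √(V̂_Q,j + 1/(3p²)),

with Ȳ_Q,j the median of the member values in sample j and
V̂_Q,j = ((k−1)/k)·var(Y_Q,j) the population-form within-cluster variance.
Z_E is approximately Student-t under the null; large |Z_E(j)| means the
members sit tightly at a common (extreme) quantile in that sample.

The association statistic Z2_E adds a moderation constant s0 and swaps
the numerator for the mean over members of (Ȳ_Q,j · y_gj):

    Z2_E(j) = √k · mean_g(Ȳ_Q,j · y_gj) / √(V̂_Q,j + 1/(3p²) + s0).

The product-mean numerator penalizes clusters that are strongly driven
except for one member moving against the rest; a `median` numerator is
available as a configuration switch.  s0 enters under the square root,
i.e. on the variance scale, the only reading consistent with the variance
terms it is added to.

### Choosing s0

s0 is selected once per run from the pooled denominator terms
(V̂ + 1/(3p²)) of all clusters × samples, in the spirit of the
"fudge factor" of moderated t statistics: candidates are 0 and the
5%…95% quantiles of the pooled terms; for each candidate the sorted terms
are split into 10 equal-count windows and the candidate minimizing the
coefficient of variation of the per-window CVs of √(term + s0) wins (ties
to the smaller s0).  The window count is exposed in the API.  Power is
quite flat in s0 on simulated data — the choice matters more for
stabilizing the Z2 scale across clusters than for ranking drivers.

## Cluster discovery

Every gene is tried as a seed:

1. **Seeding.**  Genes with Spearman ρ ≥ 0.6 to the seed form the initial
   query (Pearson on the rank-normalized matrix equals Spearman on the
   raw data); fewer than 5 or more than 20 hits are expanded/clamped to
   the 5 or 20 most-correlated genes.
2. **Two biclustering passes.**  Each pass computes Z_E, orders samples
   by decreasing |Z_E|, and picks the shortest sample prefix minimizing
   the number of non-query genes scoring above the worst query gene
   ("intrusion count"); gene similarity (s.g.i) is the negative Euclidean
   distance to the per-sample query median profile over those samples.
   The second pass re-queries with the top 10 hits of the first.  If the
   seed falls outside the top 50 of the second ranking the seed is
   abandoned.
3. **LOOCV trim and grow.**  Each member is held out and must be
   recovered within rank 10 of the non-query ranking; the worst member is
   dropped until every rank passes *and* the spread of held-out ranks is
   within a factor of 3 ("approximately equal contribution").  Growth
   then adds the top-scoring outsider, but only while the *existing*
   members' worst held-out rank does not degrade: the candidate itself is
   selected by the same score LOOCV ranks it with, so its own rank is
   biased low by construction and carries no evidence.  Clusters below 3
   members are discarded; identical member sets are deduplicated and sets
   nested inside a retained cluster are dropped.  All ranking ties break
   by gene identifier, which makes the search invariant to the row order
   of the input (rank-normalized values lie on a discrete grid, so exact
   distance ties are common, not exotic).

The search is deterministic — there is no randomness anywhere in it.

On simulated data (52 samples, 200 genes, three planted modules of sizes
5/7/10 at member correlation 0.9) the search recovers planted modules at
mean Jaccard ≈ 0.82 over 20 replicates.  On pure-noise matrices the
false-cluster rate falls with gene count (the top-50 seed gate scales
with the panel): ≈ 4% of seeds at 500 genes, ≈ 1.8% at 2,000 genes.  The
residual false clusters are small gene sets that self-validate over very
few informative samples; this is inherent to a biclustering criterion
evaluated on the samples it selected, and downstream BH adjustment over
the full cluster × SNP family is the guard the pipeline relies on.

## Association testing

For every (cluster, SNP) pair, Bartlett's k-sample variance test compares
Z2_E across the genotype classes present.  Samples missing the call are
excluded; classes with fewer than 5 remaining samples are dropped
(mirroring the marker prefilter's per-genotype floor — 2- and 4-sample
classes produce degenerate variance estimates and dominate false
positives), and pairs left with fewer than two usable classes, or with an
exactly zero-variance class, are flagged and excluded from the family.
p-values are BH-adjusted over all tested pairs jointly; the default
reporting threshold is q ≤ 0.005.

Bartlett's test is exact against an independent implementation and is
correctly calibrated on normal nulls (rejection 0.056 at α = 0.05 over
10,000 replicates of three 17-sample groups).  On real Z2 vectors it is
anti-conservative: Z2 is heavy-tailed (a variance-mixture across
samples), and Bartlett is sensitive to kurtosis.  In power simulations
(one 8-gene module, driver latent sd 0.5/1.5/3.0 by genotype class, MAF
0.3, n = 52, 99 null SNPs) the driver tops its cluster's ranking in
≈ 80–85% of replicates; the misses are null SNPs whose p-values are
inflated by exactly this kurtosis effect.  Levene/Fligner-type robust
alternatives would reduce it but are out of scope.

## Marker prefilter

A SNP is kept when (a) at most one call has confidence < 0.95 (when
confidences exist; low-confidence calls are masked to missing), (b) the
1-df chi-square Hardy-Weinberg test (no continuity correction, missing
calls excluded) gives p ≥ 0.05, and (c) at least two genotype classes
carry ≥ 5 samples each.  With n = 52 this bounds the minor allele
frequency at 5/104 ≈ 4.8% for two observed classes and 15/104 ≈ 14% for
three.

## Post-processing

* **LD pruning** — greedy over significant SNPs in ascending best-q
  order; a SNP is kept iff its composite r² (squared Pearson correlation
  of genotype codes over pairwise-complete samples) with every kept SNP
  is ≤ 0.5.  Processing in q order makes the result independent of input
  row order and keeps the most significant representative of each block.
* **Positional classes** — each SNP is assigned its nearest gene model
  (ties to the lexicographically smaller id).  Inside a transcript:
  `coding` within the CDS, `utr5`/`utr3` for exonic positions outside the
  CDS (by strand), `intron` otherwise; a transcript without an annotated
  CDS classifies all inside positions as `intron`.  Outside:
  `upstream`/`downstream` by strand, `intergenic_far` beyond 5 Mb.
  Strand affects only labels, never distances.
* **Per-gene q** — every annotated gene receives the minimum association
  q over SNPs within 5 Mb of its transcript interval (inclusive).
* **GO enrichment** — for categories with ≥ 10 assigned genes, a
  one-sided two-sample Kolmogorov–Smirnov D⁺ tests whether the category's
  gene q's are stochastically smaller than the remaining genes'.  D⁺ is
  computed from rank positions in a fixed pooled sort, for both the
  observed statistic and the permutation null (B same-sized sets drawn
  without replacement from the assigned genes), so ties are treated
  identically on both sides; p = (1 + #{null ≥ obs})/(B + 1), so p = 0 is
  impossible.  B defaults to 10,000; BH adjustment pools BP/CC/MF into
  one family by default, with a per-namespace switch.

## Baseline eQTL

Per-sample-standardized expression is regressed on genotype as an
unordered class factor (partial F test on top of optional user-supplied
covariates; surrogate-variable estimation is out of scope).  SNPs within
5 Mb of a gene form the cis family; SNPs more than 5 Mb from *every*
annotated gene are paired with all genes as the trans family; BH runs
separately per family.  A dose-coded (additive) genotype term is a
configuration switch.  Without covariates the scan uses a vectorized
one-way ANOVA identical to the textbook F test (checked against an
independent implementation and against t² for two classes).

## Synthetic data

The generator emulates a tumor-cohort design: n = 52 samples genotyped
genome-wide and assayed for expression.  Genotypes are HWE draws at MAFs
from a configurable range, placed uniformly on synthetic chromosomes.
Module members share a per-sample latent factor λ_j·u_g + ε, where
λ_j ~ N(0, sd_c(j)) and c(j) is sample j's genotype at the driver SNP,
u_g ≈ 1, and the residual sd is set from the target within-module
correlation at the heterozygote class.  The genotype therefore modulates
the *variance* of the shared factor — per-gene marginal means are
genotype-independent (median |cor(gene, driver)| → 0 as n grows), so the
planted signal is invisible to mean-based per-gene eQTL and is a pure
variance signal for the cluster-level test.  This is the one construction
under which the two methods' contrast is meaningful rather than assumed.

What the generator does not emulate: LD block structure (SNPs are
independent), probe-level noise models, batch effects, and correlated
background genes.  Passing tests therefore demonstrate the machinery and
its calibration under the stated model, not robustness to those real-data
features.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which each property is meaningfully exercised: module recovery
uses 200 genes × 52 samples × 20 replicates; power uses a 100-SNP panel
(one driver + 99 nulls) × 20–40 replicates; enrichment calibration uses
1,000 genes × 200 categories at B = 2,000 (scaled down from the 10,000
default); Bartlett calibration uses 10,000 replicates.  The null
cluster-rate measurements quoted above were run once at 500–2,000 genes.

## Numerical and design choices

* Internal coordinates are 1-based inclusive everywhere; BED's 0-based
  half-open convention is converted at the boundary and the conversion is
  involutive.
* Missing genotype calls use a dedicated sentinel (−1), never a valid
  code; every downstream operation excludes them explicitly.
* Thresholds unstated by the underlying method (ρ ≥ 0.6 seeding, top-10
  re-query, top-50 seed gate, LOOCV rank ≤ 10, rank-ratio ≤ 3, 10 s0
  windows) are defaults exposed in configuration objects, so sensitivity
  analysis requires no code change.
* VCF GQ values map to call confidences as 1 − 10^(−GQ/10).
* Zero-variance Bartlett groups, collinear eQTL covariates and
  monomorphic r² pairs yield flagged NaNs rather than infinities; flagged
  pairs shrink the BH family and are logged.

## Known limitations

* Bartlett's anti-conservatism on heavy-tailed tightness scores (above)
  means genome-wide q-values are optimistic in absolute terms; rankings
  are affected only near the top.
* The biclustering heuristic self-validates on its selected samples; at
  small gene counts the false-cluster rate is a few percent of seeds.
* Cluster discovery is O(genes × LOOCV passes) per seed and single-
  threaded; genome-scale runs (~10⁴ genes) take hours, not minutes.
* GO enrichment ignores the ontology graph (no true-path propagation);
  categories are taken as flat gene sets.
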