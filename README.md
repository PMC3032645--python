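# crequtl — co-regulatory eQTL mapping

Conventional eQTL mapping associates genetic variants with the expression
level of one transcript at a time; *trans* effects are notoriously hard to
detect this way.  `crequtl` targets a different phenotype: for each
discovered cluster of co-expressed genes it scores, per sample, how
*tightly* the cluster's members move together, and then asks — genome-wide
— whether the **variance** of that tightness differs between SNP genotype
classes.  A variant whose genotypes partition samples into strongly and
weakly co-regulated groups is a co-regulatory eQTL (creQTL), a candidate
*trans* driver of the whole module, even when no individual gene shifts
its mean expression.

The pipeline:

1. **Cluster discovery** — a recursive, rank-based biclustering heuristic:
   every gene seeds a candidate cluster from its Spearman neighbours, which
   is refined over the most informative samples and trimmed/grown under
   leave-one-out cross-validation until all members contribute
   approximately equally.
2. **Tightness scoring** — per sample j and cluster Q,

       Z2_E(j) = √k · mean_g(Ȳ_Q,j · y_gj) / √(V̂_Q,j + 1/(3p²) + s0)

   where Ȳ_Q,j is the member median in sample j, V̂_Q,j the within-cluster
   variance, and s0 a SAM-style moderation constant chosen by minimizing
   the coefficient of variation of the denominator across windows of its
   pooled distribution.
3. **Association** — Bartlett's k-sample variance test of Z2_E across
   genotype classes for every (cluster, SNP) pair, Benjamini–Hochberg
   adjusted over the full family, followed by greedy LD pruning (r² ≤ 0.5),
   positional annotation against gene models, per-gene minimum-q
   assignment within 5 Mb, and permutation-calibrated one-sided KS
   enrichment over GO categories.
4. **Baseline** — a conventional per-gene cis/trans ANOVA eQTL scan for
   side-by-side comparison.

It is written for statistical geneticists and systems biologists working
with paired genotype + expression cohorts (tens of samples, thousands of
genes, 10⁴–10⁵ markers).  Inputs are plain TSV matrices or VCF genotypes,
BED12/GFF3 gene models and a 3-column GO table; a seeded synthetic-data
generator with planted, genotype-driven modules supports end-to-end
validation.  See `docs/methods.md` for the model, parameter defaults and
known limitations.

## Worked example

Simulate a 52-sample cohort with one planted 6-gene module whose
coordination is driven by the genotype of `snp000` (latent-factor sd
0.5/1.5/3.0 for the three genotype classes), then recover both:

```python
from crequtl import rank_normalize, find_all_clusters, map_crequtl, Z2Config
from crequtl.simulate import SimulationSpec, ModuleSpec, simulate_dataset

spec = SimulationSpec(
    n_samples=52, n_genes=150, n_snps=120, maf_range=(0.25, 0.45),
    modules=[ModuleSpec(size=6, driver_snp=0,
                        tightness_by_genotype=(0.5, 1.5, 3.0))],
    rng_seed=42,
)
X, G, annotations, truth = simulate_dataset(spec)

normX = rank_normalize(X)
clusters = find_all_clusters(normX)
results = map_crequtl(clusters, normX, G, Z2Config())

module = truth.module_members[0]
match = max(clusters,
            key=lambda c: len(c.members & module) / len(c.members | module))
rows = [r for r in results if r.cluster_id == match.cluster_id]
top = min(rows, key=lambda r: (r.q, r.p))
print(f"top SNP for {match.cluster_id}: {top.snp_id} "
      f"(Bartlett={top.bartlett_stat:.1f}, p={top.p:.2e}, q={top.q:.2e})")
```

This prints:

```
top SNP for C0001: snp000 (Bartlett=31.6, p=1.37e-07, q=1.42e-05)
```

The search finds 13 clusters (the planted module — `G000…G005` plus three
hangers-on — and small spurious sets typical of biclustering at this gene
count), and the planted driver `snp000` is the minimum-q variant for the
module's cluster: genotype class 0 (latent sd 0.5) samples show loose,
near-zero tightness scores while class 2 (sd 3.0) samples are strongly
and variably driven, which is exactly the variance signal Bartlett's test
picks up.  The same data yield nothing for a per-gene trans-eQTL scan,
because the driver changes no gene's mean expression.

The same analysis is available from the shell:

```sh
crequtl simulate --outdir sim --seed 42 --genes 150 --snps 120 --modules 1
crequtl cluster --expression sim/expression.tsv --out clusters.tsv
crequtl associate --expression sim/expression.tsv --genotypes sim/genotypes.tsv \
    --clusters clusters.tsv --out associations.tsv --fdr 0.005
```

or end-to-end via `crequtl run --config pipeline.yaml`.

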