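"""Synthetic-data generator with planted genotype-driven co-expression.

The generator emulates the study design the method targets: ~52 samples
assayed for both genome-wide SNP genotypes and expression of thousands
of genes.  Genotypes are drawn under Hardy-Weinberg equilibrium at a
per-SNP minor allele frequency from ``maf_range``.  Expression is i.i.d.
noise except for planted modules: the members of a module share a
per-sample latent factor

    x_gj = lambda_j * u_g + eps_gj,
    lambda_j ~ Normal(0, sd_c(j)),   u_g ~= 1,   eps ~ Normal(0, sd_eps)

where c(j) is sample j's genotype class at the module's designated
driver SNP.  The genotype thus modulates the *variance* of the shared
factor — the spread of the module's per-sample tightness — while every
gene's marginal mean is genotype-independent.  This makes the planted
signal invisible to per-gene mean-based eQTL but detectable by a
variance test on cluster tightness, mirroring the contrast the method
is designed to expose.  ``base_correlation`` sets the within-module
gene-gene correlation at the reference (heterozygote) latent sd.

Everything is reproducible from a single seed; all stochastic steps
consume streams spawned from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, GeneAnnotation, GenotypeMatrix, SnpLocus

CHROM_LENGTH = 100_000_000


@dataclass
class ModuleSpec:
    size: int
    driver_snp: int | None = None          # index into the SNP panel, or None
    tightness_by_genotype: tuple[float, float, float] = (1.0, 1.0, 1.0)
    base_correlation: float = 0.9

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("module size must be >= 3")
        if any(t <= 0 for t in self.tightness_by_genotype):
            raise ValueError("tightness values must be > 0")
        if not 0.0 < self.base_correlation < 1.0:
            raise ValueError("base_correlation must be in (0, 1)")


@dataclass
class SimulationSpec:
    n_samples: int = 52
    n_genes: int = 2000
    n_snps: int = 20_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    modules: list[ModuleSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    n_chromosomes: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("modules do not fit in n_genes")
        for m in self.modules:
            if m.driver_snp is not None and not 0 <= m.driver_snp < self.n_snps:
                raise ValueError("driver_snp index out of range")


@dataclass
class SimulationTruth:
    module_members: list[frozenset[str]]
    driver_snps: list[str | None]
    latent_factors: list[np.ndarray]       # per-module, length n_samples


def simulate_genotypes(
    n_snps: int,
    n_samples: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
    n_chromosomes: int = 4,
) -> GenotypeMatrix:
    """HWE genotypes at random MAFs, placed uniformly on synthetic
    chromosomes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    codes = rng.binomial(2, mafs[:, None], size=(n_snps, n_samples)).astype(np.int8)
    chroms = rng.integers(1, n_chromosomes + 1, size=n_snps)
    positions = rng.integers(1, CHROM_LENGTH + 1, size=n_snps)
    width = len(str(n_snps))
    loci = [
        SnpLocus(f"chr{c}", int(p), ("A", "G"))
        for c, p in zip(chroms, positions)
    ]
    snp_ids = [f"snp{i:0{width}d}" for i in range(n_snps)]
    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    return GenotypeMatrix(snp_ids, sample_ids, codes, loci=loci)


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, GenotypeMatrix, list[GeneAnnotation], SimulationTruth]:
    """Full synthetic dataset: expression, genotypes, gene annotations
    and the planted ground truth."""
    ss = np.random.SeedSequence(spec.rng_seed)
    geno_rng, expr_rng, ann_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    G = simulate_genotypes(
        spec.n_snps, spec.n_samples, spec.maf_range, geno_rng, spec.n_chromosomes
    )
    width = len(str(spec.n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = list(G.sample_ids)
    values = expr_rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))

    members_out: list[frozenset[str]] = []
    drivers_out: list[str | None] = []
    factors_out: list[np.ndarray] = []
    next_gene = 0
    for mod in spec.modules:
        idx = np.arange(next_gene, next_gene + mod.size)
        next_gene += mod.size
        sds = np.asarray(mod.tightness_by_genotype)
        if mod.driver_snp is not None:
            codes = G.codes[mod.driver_snp]
            sd_per_sample = sds[codes]
        else:
            sd_per_sample = np.full(spec.n_samples, sds[1])
        lam = expr_rng.normal(0.0, 1.0, size=spec.n_samples) * sd_per_sample
        u = expr_rng.normal(1.0, 0.05, size=mod.size)
        # within-module correlation at the reference sd: r = sd1^2/(sd1^2+se^2)
        r = mod.base_correlation
        sd_eps = sds[1] * np.sqrt((1.0 - r) / r)
        eps = expr_rng.normal(0.0, sd_eps, size=(mod.size, spec.n_samples))
        values[idx] = lam[None, :] * u[:, None] + eps
        members_out.append(frozenset(gene_ids[i] for i in idx))
        drivers_out.append(
            None if mod.driver_snp is None else G.snp_ids[mod.driver_snp]
        )
        factors_out.append(lam)

    X = ExpressionMatrix(gene_ids, sample_ids, values)
    annotations = _simulate_annotations(gene_ids, spec.n_chromosomes, ann_rng)
    truth = SimulationTruth(members_out, drivers_out, factors_out)
    return X, G, annotations, truth


def _simulate_annotations(
    gene_ids: list[str], n_chromosomes: int, rng: np.random.Generator
) -> list[GeneAnnotation]:
    anns = []
    for gid in gene_ids:
        chrom = f"chr{rng.integers(1, n_chromosomes + 1)}"
        start = int(rng.integers(1, CHROM_LENGTH - 200_000))
        length = int(rng.integers(5_000, 100_000))
        end = start + length
        n_exons = int(rng.integers(2, 6))
        bounds = np.sort(rng.choice(
            np.arange(start + 1, end), size=2 * n_exons - 2, replace=False
        ))
        edges = [start, *bounds.tolist(), end]
        exons = [(edges[2 * i], edges[2 * i + 1]) for i in range(n_exons)]
        exons = [(s, e) for s, e in exons if s <= e]
        cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
        cds_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        anns.append(GeneAnnotation(
            gene_id=gid, chrom=chrom, strand=strand,
            tx_start=start, tx_end=end,
            cds_start=cds_start, cds_end=max(cds_start, cds_end), exons=exons,
        ))
    anns.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return anns


def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("module\tdriver_snp\tmembers\n")
        for i, (members, driver) in enumerate(
            zip(truth.module_members, truth.driver_snps)
        ):
            fh.write(f"M{i + 1}\t{driver or 'NA'}\t{','.join(sorted(members))}\n")
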