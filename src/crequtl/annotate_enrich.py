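"""Post-processing of significant creQTLs.

* LD pruning — keep one representative SNP per linkage block (greedy,
  most significant first, composite r-squared on genotype codes);
* positional classification of each SNP against the nearest gene model
  (upstream/downstream by strand, intron/coding/UTR when inside);
* per-gene q assignment — each annotated gene receives the minimum
  association q over all SNPs within a 5 MB window;
* GO enrichment — a one-sided two-sample Kolmogorov-Smirnov statistic
  (category gene q's stochastically smaller than the rest) calibrated
  against same-sized random gene sets drawn without replacement, then
  BH-adjusted across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .association import benjamini_hochberg
from .data_io import (
    MISSING,
    AssociationResult,
    GeneAnnotation,
    GenotypeMatrix,
    GOTable,
    SnpLocus,
)

logger = logging.getLogger(__name__)


@dataclass
class SnpPosition:
    snp_id: str
    nearest_gene: str | None
    klass: str          # upstream/downstream/intron/coding/utr3/utr5/intergenic_far
    distance_bp: int    # 0 when inside the gene


@dataclass
class GeneQ:
    gene_id: str
    q_min: float
    n_snps_assigned: int


@dataclass
class EnrichmentResult:
    category_id: str
    namespace: str
    size: int
    ks_stat: float
    p_perm: float
    q: float = float("nan")


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def pairwise_r2(G: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    """Squared Pearson correlation of genotype codes over pairwise-complete
    samples (composite, unphased LD).  Monomorphic pairs give NaN."""
    if len(snp_ids) < 2:
        raise ValueError("need >= 2 SNPs")
    idx = [G.snp_index(s) for s in snp_ids]
    codes = G.codes[idx].astype(float)
    codes[G.codes[idx] == MISSING] = np.nan
    n = len(idx)
    r2 = np.full((n, n), np.nan)
    np.fill_diagonal(r2, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(codes[i]) & ~np.isnan(codes[j])
            if ok.sum() < 3:
                continue
            a, b = codes[i, ok], codes[j, ok]
            if a.std() == 0 or b.std() == 0:
                logger.warning("monomorphic SNP in r2 pair (%s, %s)",
                               snp_ids[i], snp_ids[j])
                continue
            r = np.corrcoef(a, b)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


def ld_prune(
    results: list[AssociationResult],
    G: GenotypeMatrix,
    r2_max: float = 0.5,
) -> list[AssociationResult]:
    """Greedy LD pruning of significant associations.

    SNPs are processed in ascending best-q order (ties by snp_id); a SNP
    is kept iff its r-squared with every already-kept SNP is <= r2_max.
    Returns the results restricted to kept SNPs; dropped results get
    their ``pruned`` flag set in place.
    """
    if not results:
        return []
    best_q: dict[str, float] = {}
    for r in results:
        best_q[r.snp_id] = min(best_q.get(r.snp_id, np.inf), r.q)
    snp_order = sorted(best_q, key=lambda s: (best_q[s], s))
    if len(snp_order) == 1:
        return list(results)
    r2 = pairwise_r2(G, snp_order)
    pos = {s: i for i, s in enumerate(snp_order)}
    kept: list[str] = []
    for s in snp_order:
        i = pos[s]
        ok = all(
            not (r2[i, pos[k]] > r2_max)       # NaN compares False -> keep
            for k in kept
        )
        if ok:
            kept.append(s)
    kept_set = set(kept)
    out = []
    for r in results:
        if r.snp_id in kept_set:
            out.append(r)
        else:
            r.pruned = True
    logger.info("LD pruning: %d of %d SNPs kept", len(kept), len(snp_order))
    return out


# ---------------------------------------------------------------------------
# Positional classification
# ---------------------------------------------------------------------------

def _interval_distance(pos: int, start: int, end: int) -> int:
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def _classify_inside(pos: int, gene: GeneAnnotation) -> str:
    exons = gene.exons or [(gene.tx_start, gene.tx_end)]
    in_exon = any(s <= pos <= e for s, e in exons)
    if not in_exon:
        return "intron"
    if gene.cds_start is None:
        # noncoding transcript: no CDS to partition exons into UTR/coding
        return "intron"
    if gene.cds_start <= pos <= gene.cds_end:
        return "coding"
    # exonic but outside the CDS: UTR, 5'/3' by strand
    before_cds = pos < gene.cds_start
    if gene.strand == "+":
        return "utr5" if before_cds else "utr3"
    return "utr3" if before_cds else "utr5"


def classify_snp_position(
    locus: SnpLocus,
    annotations: list[GeneAnnotation],
    snp_id: str = "",
    max_dist: int = 5_000_000,
) -> SnpPosition:
    """Classify a SNP against the nearest gene model.

    Ties in distance break toward the lexicographically smaller gene id;
    with no gene within ``max_dist`` the class is ``intergenic_far``.
    """
    best: tuple[int, str, GeneAnnotation] | None = None
    for gene in annotations:
        if gene.chrom != locus.chrom:
            continue
        d = _interval_distance(locus.pos, gene.tx_start, gene.tx_end)
        if best is None or (d, gene.gene_id) < (best[0], best[1]):
            best = (d, gene.gene_id, gene)
    if best is None:
        return SnpPosition(snp_id, None, "intergenic_far", 0)
    d, _gid, gene = best
    if d > max_dist:
        return SnpPosition(snp_id, gene.gene_id, "intergenic_far", d)
    if d == 0:
        return SnpPosition(snp_id, gene.gene_id, _classify_inside(locus.pos, gene), 0)
    left_of_gene = locus.pos < gene.tx_start
    if gene.strand == "+":
        klass = "upstream" if left_of_gene else "downstream"
    else:
        klass = "downstream" if left_of_gene else "upstream"
    return SnpPosition(snp_id, gene.gene_id, klass, d)


# ---------------------------------------------------------------------------
# Per-gene q assignment
# ---------------------------------------------------------------------------

def assign_gene_q(
    results: list[AssociationResult],
    annotations: list[GeneAnnotation],
    window: int = 5_000_000,
) -> list[GeneQ]:
    """Minimum association q per gene over SNPs within ``window`` bp of
    the transcript interval (inclusive cutoff).  Genes with no SNP in
    the window are omitted."""
    best_q: dict[str, float] = {}
    snp_pos: dict[str, tuple[str, int]] = {}
    for r in results:
        if r.snp_id not in best_q or r.q < best_q[r.snp_id]:
            best_q[r.snp_id] = r.q
        snp_pos[r.snp_id] = (r.chrom, r.pos)
    out = []
    for gene in annotations:
        q_min, n_assigned = np.inf, 0
        for snp_id, (chrom, pos) in snp_pos.items():
            if chrom != gene.chrom:
                continue
            if _interval_distance(pos, gene.tx_start, gene.tx_end) <= window:
                n_assigned += 1
                q_min = min(q_min, best_q[snp_id])
        if n_assigned:
            out.append(GeneQ(gene.gene_id, float(q_min), n_assigned))
    return out


# ---------------------------------------------------------------------------
# KS enrichment
# ---------------------------------------------------------------------------

def _dplus_from_positions(sorted_pos: np.ndarray, n: int) -> np.ndarray:
    """One-sided two-sample KS D+ from category positions in the pooled
    sorted order.

    ``sorted_pos`` is (..., c) of ascending 0-based positions.  At the
    i-th category point F_cat = (i+1)/c and F_rest = (pos_i - i)/(n - c);
    D+ is the maximum difference, the evidence that category values are
    stochastically smaller than the rest.
    """
    c = sorted_pos.shape[-1]
    i = np.arange(c)
    f_cat = (i + 1) / c
    f_rest = (sorted_pos - i) / (n - c)
    return (f_cat - f_rest).max(axis=-1)


def ks_enrichment(
    gene_q: list[GeneQ],
    category_genes,
    B: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    min_size: int = 10,
) -> EnrichmentResult | None:
    """Permutation-calibrated one-sided KS enrichment of small q-values.

    The observed D+ compares the category's gene q's against the
    remaining assigned genes'; the null redraws ``B`` same-sized gene
    sets without replacement from all assigned genes.  Categories with
    fewer than ``min_size`` assigned genes are skipped (None).
    ``p_perm = (1 + #{null >= observed}) / (B + 1)``.
    """
    rng = (
        rng_seed if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ids = [g.gene_id for g in gene_q]
    qvals = np.array([g.q_min for g in gene_q])
    member_mask = np.array([g in category_genes for g in ids])
    c = int(member_mask.sum())
    n = len(ids)
    if c < min_size:
        logger.info("category below size floor (%d < %d); skipped", c, min_size)
        return None
    if c == n:
        return EnrichmentResult("", "", c, 0.0, 1.0)
    # positions of category genes in the pooled sorted order; ties broken
    # by a fixed stable sort so observed and null are treated identically
    order = np.argsort(qvals, kind="stable")
    pos_of = np.empty(n, dtype=int)
    pos_of[order] = np.arange(n)
    obs_pos = np.sort(pos_of[member_mask])
    obs = float(_dplus_from_positions(obs_pos, n))
    # vectorized null: B random c-subsets of positions, without replacement
    # (chunked so the B x n scratch array stays small)
    chunk = max(1, int(2e7) // max(n, 1))
    null_parts = []
    done = 0
    while done < B:
        b = min(chunk, B - done)
        pos = np.sort(np.argsort(rng.random((b, n)), axis=1)[:, :c], axis=1)
        null_parts.append(_dplus_from_positions(pos, n))
        done += b
    null = np.concatenate(null_parts)
    p_perm = float((1 + (null >= obs - 1e-12).sum()) / (B + 1))
    return EnrichmentResult("", "", c, obs, p_perm)


def run_go_enrichment(
    gene_q: list[GeneQ],
    go: GOTable,
    B: int = 10_000,
    seed: int = 0,
    min_size: int = 10,
    per_namespace_fdr: bool = False,
) -> list[EnrichmentResult]:
    """KS enrichment for every qualifying GO category, BH-adjusted across
    all tested categories (one family by default; per-namespace optional).
    Sorted by (q, category_id)."""
    ss = np.random.SeedSequence(seed)
    results: list[EnrichmentResult] = []
    for cat in sorted(go.categories):
        ns, members = go.categories[cat]
        child = np.random.default_rng(ss.spawn(1)[0])
        res = ks_enrichment(gene_q, members, B=B, rng_seed=child, min_size=min_size)
        if res is None:
            continue
        res.category_id = cat
        res.namespace = ns
        results.append(res)
    if not results:
        return []
    if per_namespace_fdr:
        for ns in ("BP", "CC", "MF"):
            sub = [r for r in results if r.namespace == ns]
            if sub:
                qs = benjamini_hochberg(np.array([r.p_perm for r in sub]))
                for r, q in zip(sub, qs):
                    r.q = float(q)
    else:
        qs = benjamini_hochberg(np.array([r.p_perm for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
    results.sort(key=lambda r: (r.q, r.category_id))
    return results


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("category_id\tnamespace\tsize\tks_stat\tp_perm\tq\n")
        for r in results:
            fh.write(
                f"{r.category_id}\t{r.namespace}\t{r.size}\t"
                f"{r.ks_stat:.17g}\t{r.p_perm:.17g}\t{r.q:.17g}\n"
            )


def write_snp_positions(positions: list[SnpPosition], path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tnearest_gene\tposition\tdistance_bp\n")
        for p in positions:
            fh.write(
                f"{p.snp_id}\t{p.nearest_gene or 'NA'}\t{p.klass}\t{p.distance_bp}\n"
            )
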