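"""Baseline per-gene cis/trans eQTL by ANOVA.

The comparison analysis the cluster-level method is judged against:
each gene's per-sample-standardized expression is regressed on genotype
as an unordered class factor (plus optional user-supplied covariates),
with the genotype effect assessed by a partial F test.  SNPs within
5 MB of a gene form the cis family; SNPs more than 5 MB from *every*
annotated gene form the trans family (tested against all genes).  BH
adjustment is applied separately within each family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .association import benjamini_hochberg
from .data_io import MISSING, ExpressionMatrix, GeneAnnotation, GenotypeMatrix

logger = logging.getLogger(__name__)

CIS_WINDOW = 5_000_000


@dataclass
class EqtlResult:
    gene_id: str
    snp_id: str
    mode: str           # "cis" or "trans"
    F_stat: float
    p: float
    q: float = float("nan")


def anova_eqtl(
    expr: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial F test for a genotype-class effect on one gene.

    Samples with a missing genotype call are excluded.  Without
    covariates this is one-way ANOVA; with covariates the genotype
    factor is tested on top of the covariate-only model.  Collinear
    covariates yield (nan, nan).
    """
    expr = np.asarray(expr, dtype=float)
    genotypes = np.asarray(genotypes)
    valid = genotypes != MISSING
    y = expr[valid]
    g = genotypes[valid]
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need >= 2 genotype classes present")
    if covariates is None:
        groups = [y[g == lab] for lab in labels]
        return _oneway_f(groups)
    import statsmodels.api as sm

    Z = np.asarray(covariates, dtype=float)[valid]
    if Z.ndim == 1:
        Z = Z[:, None]
    dummies = np.column_stack([(g == lab).astype(float) for lab in labels[1:]])
    X_full = sm.add_constant(np.column_stack([dummies, Z]), has_constant="add")
    X_red = sm.add_constant(Z, has_constant="add")
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_num = X_full.shape[1] - X_red.shape[1]
    df_den = len(y) - np.linalg.matrix_rank(X_full)
    if df_den <= 0 or full.ssr >= red.ssr or np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        logger.warning("collinear or degenerate design; eQTL F undefined")
        return float("nan"), float("nan")
    F = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    return float(F), float(scipy.stats.f.sf(F, df_num, df_den))


def _oneway_f(groups: list[np.ndarray]) -> tuple[float, float]:
    k = len(groups)
    ns = np.array([len(v) for v in groups], dtype=float)
    N = ns.sum()
    means = np.array([v.mean() for v in groups])
    grand = np.concatenate(groups).mean()
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = sum(((v - m) ** 2).sum() for v, m in zip(groups, means))
    if ssw == 0:
        return float("inf"), 0.0
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return float(F), float(scipy.stats.f.sf(F, k - 1, N - k))


def _oneway_f_matrix(Y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA of every row of Y (genes x samples) on the genotype
    vector g, vectorized over genes."""
    labels = np.unique(g)
    k = len(labels)
    N = Y.shape[1]
    grand = Y.mean(axis=1)
    ssb = np.zeros(Y.shape[0])
    ssw = np.zeros(Y.shape[0])
    for lab in labels:
        sub = Y[:, g == lab]
        m = sub.mean(axis=1)
        ssb += sub.shape[1] * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (N - k))
    F = np.where(ssw == 0, np.inf, F)
    p = scipy.stats.f.sf(F, k - 1, N - k)
    return F, p


def run_cis_trans_eqtl(
    X: ExpressionMatrix,
    G: GenotypeMatrix,
    annotations: list[GeneAnnotation],
    covariates: np.ndarray | None = None,
    window: int = CIS_WINDOW,
) -> tuple[list[EqtlResult], list[EqtlResult]]:
    """Genome-wide cis and trans eQTL scans with separate BH families.

    ``X`` must already be per-sample standardized.  cis pairs are
    (gene, SNP within ``window`` of the gene's transcript); the trans
    family pairs every gene with each SNP more than ``window`` from
    every annotated gene.  The two families are disjoint by construction.
    """
    if G.loci is None:
        raise ValueError("genotypes need loci for cis/trans classification")
    if list(G.sample_ids) != list(X.sample_ids):
        raise ValueError("genotype and expression sample IDs differ")
    ann_by_gene = {a.gene_id: a for a in annotations}
    # classify each SNP: near-gene set (for cis) and far-from-everything flag
    cis_pairs: list[tuple[int, int]] = []        # (gene_idx, snp_idx)
    trans_snps: list[int] = []
    for s, loc in enumerate(G.loci):
        near_any = False
        for gi, gene_id in enumerate(X.gene_ids):
            a = ann_by_gene.get(gene_id)
            if a is None or a.chrom != loc.chrom:
                continue
            d = _dist(loc.pos, a.tx_start, a.tx_end)
            if d <= window:
                cis_pairs.append((gi, s))
        for a in annotations:
            if a.chrom == loc.chrom and _dist(loc.pos, a.tx_start, a.tx_end) <= window:
                near_any = True
                break
        if not near_any:
            trans_snps.append(s)

    cis = _scan_pairs(X, G, cis_pairs, "cis", covariates)
    trans_pairs = [(gi, s) for s in trans_snps for gi in range(X.n_genes)]
    trans = _scan_pairs(X, G, trans_pairs, "trans", covariates)
    logger.info("eQTL: %d cis tests, %d trans tests", len(cis), len(trans))
    return cis, trans


def _dist(pos: int, start: int, end: int) -> int:
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def _scan_pairs(
    X: ExpressionMatrix,
    G: GenotypeMatrix,
    pairs: list[tuple[int, int]],
    mode: str,
    covariates: np.ndarray | None,
) -> list[EqtlResult]:
    if not pairs:
        return []
    results: list[EqtlResult] = []
    if covariates is None:
        # group pairs by SNP so the vectorized ANOVA runs once per SNP
        by_snp: dict[int, list[int]] = {}
        for gi, s in pairs:
            by_snp.setdefault(s, []).append(gi)
        for s, gidx in sorted(by_snp.items()):
            codes = G.codes[s]
            valid = codes != MISSING
            g = codes[valid]
            if len(np.unique(g)) < 2:
                continue
            F, p = _oneway_f_matrix(X.values[np.asarray(gidx)][:, valid], g)
            for gi, Fi, pi in zip(gidx, F, p):
                results.append(EqtlResult(X.gene_ids[gi], G.snp_ids[s], mode,
                                          float(Fi), float(pi)))
    else:
        for gi, s in pairs:
            codes = G.codes[s]
            if len(np.unique(codes[codes != MISSING])) < 2:
                continue
            F, p = anova_eqtl(X.values[gi], codes, covariates)
            if np.isnan(p):
                continue
            results.append(EqtlResult(X.gene_ids[gi], G.snp_ids[s], mode,
                                      float(F), float(p)))
    if results:
        qs = benjamini_hochberg(np.array([r.p for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
        results.sort(key=lambda r: (r.q, r.snp_id, r.gene_id))
    return results


def write_eqtl(results: list[EqtlResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsnp_id\tmode\tF_stat\tp\tq\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.snp_id}\t{r.mode}\t"
                f"{r.F_stat:.17g}\t{r.p:.17g}\t{r.q:.17g}\n"
            )
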