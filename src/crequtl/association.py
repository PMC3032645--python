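"""The creQTL association test.

For each discovered cluster, every sample gets a moderated tightness
score

    Z2_E(j) = sqrt(k_j) * N_j / sqrt(Vhat_Q,j + 1/(3 p^2) + s0)

where the numerator N_j is, by default, the mean over member genes of
(median member value in sample j) x (that gene's value in sample j) —
this penalizes clusters that are strongly driven except for a weakly
driven outlier — or optionally the plain median.  The moderation
constant s0 is shared by the whole run and chosen SAM-style: it
minimizes the coefficient of variation of the denominator across
equal-count windows of the pooled denominator distribution.

A genetic variant is a creQTL for a cluster when the *variance* of
Z2_E differs across its genotype classes (Bartlett's k-sample test);
genotype does not need to shift the mean tightness, only its spread.
p-values are Benjamini-Hochberg adjusted over the full cluster x SNP
family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .cluster_search import GeneCluster
from .data_io import MISSING, AssociationResult, ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class Z2Config:
    numerator_mode: str = "mean_of_products"   # or "median"
    s0: float | str = "auto"
    fdr_threshold: float = 0.005

    def __post_init__(self) -> None:
        if self.numerator_mode not in ("mean_of_products", "median"):
            raise ValueError(f"unknown numerator mode {self.numerator_mode!r}")
        if isinstance(self.s0, str):
            if self.s0 != "auto":
                raise ValueError("s0 must be a non-negative number or 'auto'")
        elif self.s0 < 0:
            raise ValueError("s0 must be >= 0")


def denominator_terms(normX: ExpressionMatrix, cluster: GeneCluster) -> np.ndarray:
    """Per-sample variance terms Vhat_Q,j + 1/(3 p^2) for one cluster."""
    qidx = np.asarray(sorted(normX.gene_index(g) for g in cluster.members))
    Y = normX.values[qidx]
    p = normX.n_samples
    return Y.var(axis=0, ddof=0) + 1.0 / (3.0 * p * p)


def compute_Z2E(
    normX: ExpressionMatrix,
    cluster: GeneCluster,
    s0: float = 0.0,
    mode: str = "mean_of_products",
) -> np.ndarray:
    """Moderated per-sample tightness scores for one cluster."""
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    qidx = np.asarray(sorted(normX.gene_index(g) for g in cluster.members))
    Y = normX.values[qidx]
    k = Y.shape[0]
    p = normX.n_samples
    ybar = np.median(Y, axis=0)
    if mode == "mean_of_products":
        numerator = (ybar[None, :] * Y).mean(axis=0)
    elif mode == "median":
        numerator = ybar
    else:
        raise ValueError(f"unknown numerator mode {mode!r}")
    vhat = Y.var(axis=0, ddof=0)
    return np.sqrt(k) * numerator / np.sqrt(vhat + 1.0 / (3.0 * p * p) + s0)


def choose_s0(terms: np.ndarray, n_windows: int = 10) -> float:
    """SAM-style moderation constant.

    Candidates are 0 and the 5%..95% quantiles (step 5%) of the pooled
    denominator terms.  For each candidate the sorted values are split
    into ``n_windows`` equal-count windows; the candidate minimizing the
    coefficient of variation of the per-window CVs of sqrt(term + s0)
    wins, ties to the smaller s0.
    """
    terms = np.sort(np.asarray(terms, dtype=float))
    if terms.size < 10:
        raise ValueError("need >= 10 denominator terms to choose s0")
    if terms[0] == terms[-1]:
        return 0.0
    quantiles = np.quantile(terms, np.arange(0.05, 0.96, 0.05))
    candidates = np.concatenate([[0.0], quantiles])
    candidates = np.unique(candidates)          # ascending, so ties -> smaller
    best_s0, best_score = 0.0, np.inf
    windows = np.array_split(terms, n_windows)
    for s0 in candidates:
        cvs = []
        for w in windows:
            x = np.sqrt(w + s0)
            m = x.mean()
            cvs.append(x.std(ddof=0) / m if m > 0 else np.inf)
        cvs = np.asarray(cvs)
        m = cvs.mean()
        score = cvs.std(ddof=0) / m if m > 0 else np.inf
        if score < best_score:
            best_s0, best_score = float(s0), float(score)
    return best_s0


def bartlett_test(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Bartlett's k-sample variance-homogeneity test.

    Returns (statistic, p) with a chi-square (k-1 df) null.  Every group
    must carry >= 2 values; a group with exactly zero variance makes the
    statistic undefined and yields (nan, nan).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    ns, variances = [], []
    for lab in labels:
        v = values[groups == lab]
        if v.size < 2:
            raise ValueError("every group needs >= 2 values")
        ns.append(v.size)
        variances.append(v.var(ddof=1))
    ns = np.asarray(ns, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if (variances == 0).any():
        logger.warning("zero-variance group in Bartlett test; p undefined")
        return float("nan"), float("nan")
    k = len(ns)
    N = ns.sum()
    sp2 = ((ns - 1) * variances).sum() / (N - k)
    T = (N - k) * np.log(sp2) - ((ns - 1) * np.log(variances)).sum()
    C = 1.0 + ((1.0 / (ns - 1)).sum() - 1.0 / (N - k)) / (3.0 * (k - 1))
    stat = T / C
    return float(stat), float(scipy.stats.chi2.sf(stat, df=k - 1))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def map_crequtl(
    clusters: list[GeneCluster],
    normX: ExpressionMatrix,
    G: GenotypeMatrix,
    cfg: Z2Config | None = None,
    min_group_size: int = 5,
) -> list[AssociationResult]:
    """Test every (cluster, SNP) pair.

    s0 is chosen once from the pooled denominator terms of all clusters
    (when cfg.s0 == "auto").  For each SNP, samples with a missing call
    are excluded and genotype classes with fewer than ``min_group_size``
    remaining samples are dropped (default 5, matching the marker
    prefilter's per-genotype floor: tiny classes give degenerate
    variance estimates); pairs left with < 2 usable classes, or with a
    zero-variance class, are flagged NaN and excluded from the BH
    family.  Results come back sorted by (q, snp_id, cluster_id).
    """
    cfg = cfg or Z2Config()
    if not clusters:
        return []
    if list(G.sample_ids) != list(normX.sample_ids):
        raise ValueError("genotype and expression sample IDs differ")
    if cfg.s0 == "auto":
        pooled = np.concatenate([denominator_terms(normX, c) for c in clusters])
        s0 = choose_s0(pooled)
        logger.info("auto-selected s0 = %.6g from %d terms", s0, pooled.size)
    else:
        s0 = float(cfg.s0)
    Z2 = {
        c.cluster_id: compute_Z2E(normX, c, s0=s0, mode=cfg.numerator_mode)
        for c in clusters
    }
    loci = G.loci or [None] * G.n_snps
    records = []          # (cluster, snp_idx, group_sizes, stat, p)
    n_flagged = 0
    for s in range(G.n_snps):
        codes = G.codes[s]
        valid = codes != MISSING
        usable_labels = [
            lab for lab in (0, 1, 2)
            if int(((codes == lab) & valid).sum()) >= max(2, min_group_size)
        ]
        if len(usable_labels) < 2:
            n_flagged += len(clusters)
            continue
        mask = valid & np.isin(codes, usable_labels)
        g = codes[mask]
        sizes = tuple(int((g == lab).sum()) for lab in usable_labels)
        for c in clusters:
            stat, p = bartlett_test(Z2[c.cluster_id][mask], g)
            if np.isnan(p):
                n_flagged += 1
                continue
            records.append((c, s, sizes, stat, p))
    if n_flagged:
        logger.warning("%d (cluster, SNP) pairs untestable; excluded from BH", n_flagged)
    if not records:
        return []
    qvals = benjamini_hochberg(np.array([r[4] for r in records]))
    results = []
    for (c, s, sizes, stat, p), q in zip(records, qvals):
        loc = loci[s]
        results.append(AssociationResult(
            cluster_id=c.cluster_id,
            snp_id=G.snp_ids[s],
            chrom=loc.chrom if loc else "",
            pos=loc.pos if loc else 0,
            member_genes=tuple(sorted(c.members)),
            group_sizes=sizes,
            bartlett_stat=stat,
            p=float(p),
            q=float(q),
        ))
    results.sort(key=lambda r: (r.q, r.snp_id, r.cluster_id))
    logger.info(
        "creQTL scan: %d tests over %d clusters x %d SNPs",
        len(results), len(clusters), G.n_snps,
    )
    return results
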