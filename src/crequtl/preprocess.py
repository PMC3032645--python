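"""Expression and SNP prefilters plus the two normalizations.

Two distinct normalizations are used downstream:

* :func:`rank_normalize` — per-gene rank transform to an equally spaced
  grid with mean 0 and population variance exactly 1/3, the input the
  rank-based biclustering core expects;
* :func:`standardize_per_sample` — per-sample (column) standardization to
  mean 0 / variance 1, the input the baseline eQTL ANOVA expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .data_io import MISSING, ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SnpFilterConfig:
    """Marker prefilter thresholds.

    Defaults mirror a stringent SNP-array QC: call confidence >= 0.95 in
    all but one sample, Hardy-Weinberg equilibrium at alpha 0.05, and at
    least two genotype classes each carrying >= 5 samples (which bounds
    the minor allele frequency at 5/2n for two observed classes).
    """

    min_call_conf: float = 0.95
    max_lowconf_samples: int = 1
    hwe_alpha: float = 0.05
    min_group_size: int = 5
    min_groups: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_conf <= 1.0:
            raise ValueError("min_call_conf must be in [0, 1]")
        if self.max_lowconf_samples < 0:
            raise ValueError("max_lowconf_samples must be >= 0")
        if not 0.0 <= self.hwe_alpha <= 1.0:
            raise ValueError("hwe_alpha must be in [0, 1]")
        if self.min_group_size < 1 or self.min_groups < 1:
            raise ValueError("group thresholds must be positive")


def filter_expression_by_variance(
    X: ExpressionMatrix, drop_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop the lowest-variance genes.

    Genes whose sample variance falls strictly below the ``drop_fraction``
    quantile of all per-gene variances are removed; ties at the threshold
    are retained.  ``drop_fraction=0`` is the identity.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    if X.n_samples < 2:
        raise ValueError("need >= 2 samples to compute variances")
    if drop_fraction == 0.0:
        return X
    variances = X.values.var(axis=1, ddof=1)
    threshold = np.quantile(variances, drop_fraction)
    keep = variances >= threshold
    logger.info("variance filter: %d of %d genes retained", keep.sum(), X.n_genes)
    return X.subset_genes(keep)


def rank_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene rank transform to an equally spaced symmetric grid.

    Ranks r in {1..p} (mid-ranks for ties) map to
    ``a * (2(r-1)/(p-1) - 1)`` with ``a = sqrt((p-1)/(p+1))``, so a gene
    with p distinct values has mean exactly 0 and population variance
    exactly 1/3.  The transform is monotone within each gene, hence
    invariant to any strictly increasing per-gene transform of the input.
    A gene constant across all samples maps to an all-zero row.
    """
    p = X.n_samples
    if p < 2:
        raise ValueError("need >= 2 samples to rank-normalize")
    a = np.sqrt((p - 1) / (p + 1))
    out = np.empty_like(X.values)
    for i in range(X.n_genes):
        row = X.values[i]
        if np.ptp(row) == 0.0:
            logger.warning("gene %s constant across samples; set to 0", X.gene_ids[i])
            out[i] = 0.0
            continue
        r = scipy.stats.rankdata(row, method="average")
        out[i] = a * (2.0 * (r - 1.0) / (p - 1.0) - 1.0)
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), out)


def standardize_per_sample(X: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each sample (column) to mean 0 and sample variance 1."""
    if X.n_genes < 2:
        raise ValueError("need >= 2 genes to standardize samples")
    mean = X.values.mean(axis=0)
    sd = X.values.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    if degenerate.any():
        bad = X.sample_ids[int(np.flatnonzero(degenerate)[0])]
        raise ValueError(f"sample {bad} is constant across genes")
    return ExpressionMatrix(
        list(X.gene_ids), list(X.sample_ids), (X.values - mean) / sd
    )


def hwe_test(n0: int, n1: int, n2: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg
    equilibrium from genotype counts (no continuity correction).

    Expected counts derive from the observed allele frequencies; a
    monomorphic marker (one allele absent) fits HWE exactly and returns 1.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("all genotype counts are zero")
    p_allele = (2 * n0 + n1) / (2 * n)
    q_allele = 1.0 - p_allele
    expected = np.array([n * p_allele**2, 2 * n * p_allele * q_allele, n * q_allele**2])
    observed = np.array([n0, n1, n2], dtype=float)
    nz = expected > 0
    chi2 = float(((observed[nz] - expected[nz]) ** 2 / expected[nz]).sum())
    return float(scipy.stats.chi2.sf(chi2, df=1))


def genotype_counts(codes_row: np.ndarray) -> tuple[int, int, int]:
    """Counts of codes 0/1/2 in one SNP row, ignoring missing calls."""
    valid = codes_row[codes_row != MISSING]
    return (
        int((valid == 0).sum()), int((valid == 1).sum()), int((valid == 2).sum())
    )


def filter_snps(G: GenotypeMatrix, cfg: SnpFilterConfig | None = None) -> GenotypeMatrix:
    """Apply the marker prefilter.

    A SNP is retained iff (a) at most ``max_lowconf_samples`` calls fall
    below ``min_call_conf`` (when confidences are present), (b) its HWE
    chi-square p-value is >= ``hwe_alpha``, and (c) at least ``min_groups``
    genotype classes each carry >= ``min_group_size`` samples.  Low-
    confidence and missing calls are set to the missing sentinel in the
    output so downstream tests exclude those samples.
    """
    cfg = cfg or SnpFilterConfig()
    codes = G.codes.copy()
    if G.confidences is not None:
        lowconf = (G.confidences < cfg.min_call_conf) & (codes != MISSING)
        n_lowconf = lowconf.sum(axis=1)
        codes[lowconf] = MISSING
    else:
        n_lowconf = np.zeros(G.n_snps, dtype=int)
    keep = np.zeros(G.n_snps, dtype=bool)
    for i in range(G.n_snps):
        if n_lowconf[i] > cfg.max_lowconf_samples:
            continue
        n0, n1, n2 = genotype_counts(codes[i])
        if n0 + n1 + n2 == 0:
            continue
        if hwe_test(n0, n1, n2) < cfg.hwe_alpha:
            continue
        big_groups = sum(c >= cfg.min_group_size for c in (n0, n1, n2) if c > 0)
        if big_groups < cfg.min_groups:
            continue
        keep[i] = True
    logger.info("SNP filter: %d of %d SNPs retained", keep.sum(), G.n_snps)
    out = G.subset_snps(keep)
    out.codes = codes[keep]
    return out
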