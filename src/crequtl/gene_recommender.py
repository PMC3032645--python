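"""Rank-based biclustering core ("Gene Recommender" style).

Given rank-normalized expression and a query set of putatively
co-regulated genes, the algorithm

1. scores every sample's cluster tightness with the statistic
   ``Z_E(j) = sqrt(k_j) * median(Y_Q,j) / sqrt(Vhat_Q,j + 1/(3 p^2))``,
   where ``Vhat_Q,j = ((k_j - 1)/k_j) var(Y_Q,j)`` is the population-form
   variance of the query genes in sample j and p is the sample count
   (Z_E has an approximate Student-t null distribution);
2. selects the most informative samples: samples are ordered by
   decreasing |Z_E| and the shortest prefix minimizing the number of
   non-query genes intruding above the worst query gene is kept;
3. ranks every gene by its similarity score ("s.g.i"), the negative
   Euclidean distance to the per-sample query median profile over the
   selected samples.

Larger Z_E means tighter coordinated regulation in that sample; larger
(less negative) s.g.i means closer to the query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix


@dataclass
class GRResult:
    query: frozenset[str]
    ZE: np.ndarray                      # per-sample tightness scores
    selected_experiments: list[str]     # informative samples, |Z_E| order
    sgi: np.ndarray                     # per-gene similarity, input gene order
    ranking: list[str]                  # all genes, descending s.g.i


def _query_indices(normX: ExpressionMatrix, query) -> np.ndarray:
    lookup = normX._gene_lookup()
    try:
        idx = sorted(lookup[g] for g in query)
    except KeyError as exc:
        raise KeyError(f"query gene {exc.args[0]!r} not in expression matrix") from None
    return np.asarray(idx, dtype=int)


def compute_ZE(normX: ExpressionMatrix, query) -> np.ndarray:
    """Per-sample cluster-tightness scores for a query gene set."""
    qidx = _query_indices(normX, query)
    if len(qidx) < 2:
        raise ValueError("query must contain at least 2 genes")
    Y = normX.values[qidx]                       # k x p
    k = Y.shape[0]
    p = normX.n_samples
    ybar = np.median(Y, axis=0)
    vhat = Y.var(axis=0, ddof=0)                 # ((k-1)/k) * sample variance
    return np.sqrt(k) * ybar / np.sqrt(vhat + 1.0 / (3.0 * p * p))


def _prefix_distances(normX: ExpressionMatrix, qidx: np.ndarray, order: np.ndarray):
    """Cumulative squared distances of every gene to the query median
    profile, accumulated in the given sample order.

    Returns a (genes x p) matrix whose column m-1 holds the squared
    distance over the first m samples of ``order``.
    """
    med = np.median(normX.values[qidx], axis=0)  # per-sample query median
    sq = (normX.values - med) ** 2               # genes x p
    return np.cumsum(sq[:, order], axis=1)


def select_experiments(ZE: np.ndarray, normX: ExpressionMatrix, query) -> list[str]:
    """Choose the informative samples for a query.

    Samples are sorted by decreasing |Z_E|.  Each prefix of length
    m in {2..p} is scored by the number of non-query genes whose
    prefix-restricted s.g.i exceeds the minimum query-gene s.g.i
    (the "intrusion count"); the shortest prefix attaining the minimal
    count wins.
    """
    p = normX.n_samples
    if p < 2:
        raise ValueError("need >= 2 samples")
    qidx = _query_indices(normX, query)
    order = np.argsort(-np.abs(ZE), kind="stable")
    cum = _prefix_distances(normX, qidx, order)
    nonq = np.setdiff1d(np.arange(normX.n_genes), qidx)
    # sgi = -sqrt(cum) is monotone decreasing in cum, so "sgi > min query
    # sgi" is exactly "cum < max query cum"; no sqrt needed here.
    worst_query = cum[qidx].max(axis=0)                    # per prefix length
    counts = (cum[nonq] < worst_query[None, :]).sum(axis=0)
    best_m = 2 + int(np.argmin(counts[1:]))                # ties -> smaller m
    return [normX.sample_ids[i] for i in order[:best_m]]


def score_genes(normX: ExpressionMatrix, query, experiments: list[str]) -> np.ndarray:
    """s.g.i for every gene: negative Euclidean distance to the query
    median profile over the selected samples (0 = identical)."""
    if not experiments:
        raise ValueError("experiments must be non-empty")
    qidx = _query_indices(normX, query)
    lookup = {s: j for j, s in enumerate(normX.sample_ids)}
    eidx = np.asarray([lookup[s] for s in experiments], dtype=int)
    med = np.median(normX.values[qidx][:, eidx], axis=0)
    sq = (normX.values[:, eidx] - med) ** 2
    return -np.sqrt(sq.sum(axis=1))


def run_gr(normX: ExpressionMatrix, query) -> GRResult:
    """Full pass: tightness scores, informative-sample selection, ranking.

    Equivalent to compute_ZE -> select_experiments -> score_genes, fused
    so the query median profile and the distance accumulations are
    computed once.  Deterministic given its inputs; ranking ties break
    by input gene order.
    """
    qidx = _query_indices(normX, query)
    if len(qidx) < 2:
        raise ValueError("query must contain at least 2 genes")
    V = normX.values
    Y = V[qidx]
    k = Y.shape[0]
    p = normX.n_samples
    if p < 2:
        raise ValueError("need >= 2 samples")
    ybar = np.median(Y, axis=0)
    vhat = Y.var(axis=0, ddof=0)
    ZE = np.sqrt(k) * ybar / np.sqrt(vhat + 1.0 / (3.0 * p * p))

    order = np.argsort(-np.abs(ZE), kind="stable")
    sq = (V - ybar) ** 2
    cum = np.cumsum(sq[:, order], axis=1)
    qmask = np.zeros(normX.n_genes, dtype=bool)
    qmask[qidx] = True
    worst_query = cum[qidx].max(axis=0)
    counts = (cum[~qmask] < worst_query[None, :]).sum(axis=0)
    best_m = 2 + int(np.argmin(counts[1:]))
    experiments = [normX.sample_ids[i] for i in order[:best_m]]

    sgi = -np.sqrt(cum[:, best_m - 1])
    # rank-normalized values lie on a discrete grid, so distance ties are
    # common; break them by gene id to stay row-order independent
    rank_order = np.lexsort((normX._lex_rank(), -sgi))
    ranking = [normX.gene_ids[i] for i in rank_order]
    return GRResult(
        query=frozenset(query),
        ZE=ZE,
        selected_experiments=experiments,
        sgi=sgi,
        ranking=ranking,
    )
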