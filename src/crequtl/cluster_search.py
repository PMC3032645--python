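"""Genome-wide recursive cluster discovery.

Every gene is tried as a seed.  An initial query is formed from the
seed's Spearman neighbours (clamped to 5-20 genes), refined through two
biclustering passes, sanity-checked (the seed must land within the top
50 of the second ranking), then trimmed and grown under leave-one-out
cross-validation until all members contribute approximately equally:
each member, held out, must be recovered within ``loocv_rank_threshold``
of the non-query ranking, and the spread of held-out ranks must stay
within a factor of 3.

Because the input is already rank-normalized (a monotone per-gene
transform of ranks), Pearson correlation on it equals Spearman
correlation on the raw data; neighbour search exploits this.

The search has no randomness: identical input and config give identical
output, and the result is invariant to gene-row permutation up to
cluster labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix
from .gene_recommender import run_gr

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    rho_min: float = 0.6          # Spearman threshold for "highly correlated"
    seed_min: int = 5             # clamp window for the initial query
    seed_max: int = 20
    rerun_top: int = 10           # query size for the second pass
    seed_rank_limit: int = 50     # seed must score within this after pass 2
    loocv_rank_threshold: int = 10
    max_add_steps: int = 20
    max_rank_ratio: float = 3.0   # "approximately equal contribution"

    def __post_init__(self) -> None:
        if not 2 <= self.seed_min <= self.seed_max:
            raise ValueError("need 2 <= seed_min <= seed_max")
        for name in ("rerun_top", "seed_rank_limit", "loocv_rank_threshold",
                     "max_add_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GeneCluster:
    cluster_id: str
    seed_gene: str
    members: frozenset[str]
    loocv_ranks: dict[str, int] = field(default_factory=dict)
    selected_experiments: list[str] = field(default_factory=list)


def _spearman_to_seed(normX: ExpressionMatrix, seed_idx: int) -> np.ndarray:
    """Correlation of every gene with the seed on the rank-normalized
    matrix (= Spearman on the raw data).  Constant genes get rho 0."""
    V = normX.values
    centered = V - V.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    s = centered[seed_idx]
    s_norm = norms[seed_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = centered @ s / (norms * s_norm)
    rho[~np.isfinite(rho)] = 0.0
    return rho


def seed_query(normX: ExpressionMatrix, seed_gene: str, cfg: SearchConfig) -> frozenset[str]:
    """Initial query: genes with Spearman rho >= rho_min to the seed,
    clamped to [seed_min, seed_max] most-correlated genes (seed always in)."""
    seed_idx = normX.gene_index(seed_gene)
    rho = _spearman_to_seed(normX, seed_idx)
    hits = set(np.flatnonzero(rho >= cfg.rho_min))
    hits.add(seed_idx)
    if len(hits) < cfg.seed_min or len(hits) > cfg.seed_max:
        target = cfg.seed_min if len(hits) < cfg.seed_min else cfg.seed_max
        # ties in rho break by gene id (row-order independence)
        order = np.lexsort((normX._lex_rank(), -rho))
        top = list(order[:target])
        if seed_idx not in top:
            top = [seed_idx] + top[: target - 1]
        hits = set(top)
    return frozenset(normX.gene_ids[i] for i in hits)


def loocv_scores(normX: ExpressionMatrix, members) -> dict[str, int]:
    """Held-out rank per member: position of the held-out gene in the
    non-query part of the ranking produced by the remaining members
    (1 = best possible recovery)."""
    members = list(members)
    if len(members) < 3:
        raise ValueError("LOOCV needs >= 3 members (query must stay >= 2)")
    ranks: dict[str, int] = {}
    for g in members:
        rest = frozenset(m for m in members if m != g)
        res = run_gr(normX, rest)
        rank = 0
        for gene in res.ranking:
            if gene in rest:
                continue
            rank += 1
            if gene == g:
                break
        ranks[g] = rank
    return ranks


def refine_cluster(
    normX: ExpressionMatrix, seed_gene: str, cfg: SearchConfig | None = None
) -> GeneCluster | None:
    """Run the full per-seed pipeline; None if no tight cluster survives."""
    cfg = cfg or SearchConfig()
    query = seed_query(normX, seed_gene, cfg)
    first = run_gr(normX, query)
    second_query = frozenset(first.ranking[: cfg.rerun_top])
    second = run_gr(normX, second_query)
    if second.ranking.index(seed_gene) + 1 > cfg.seed_rank_limit:
        return None

    def converged(ranks: dict[str, int]) -> bool:
        # every member recovered within the threshold AND approximately
        # equal contribution (bounded spread of held-out ranks)
        values = list(ranks.values())
        return (max(values) <= cfg.loocv_rank_threshold
                and max(values) / min(values) <= cfg.max_rank_ratio)

    members = set(second_query)
    ranks = loocv_scores(normX, members)
    # trim: drop the worst-recovered member until the cluster converges
    while not converged(ranks):
        if len(members) <= 3:
            return None
        worst = max(sorted(members), key=lambda g: ranks[g])
        members.discard(worst)
        ranks = loocv_scores(normX, members)

    # grow: add next-best non-members, stringently.  The candidate is the
    # top-scoring outsider, so its own held-out rank is biased low by
    # construction; the real acceptance evidence is that the *existing*
    # members' recovery does not degrade (max held-out rank not worsened).
    for _ in range(cfg.max_add_steps):
        res = run_gr(normX, members)
        candidate = next((g for g in res.ranking if g not in members), None)
        if candidate is None:
            break
        trial = members | {candidate}
        trial_ranks = loocv_scores(normX, trial)
        if converged(trial_ranks) and max(trial_ranks.values()) <= max(ranks.values()):
            members, ranks = trial, trial_ranks
        else:
            break

    if len(members) < 3 or not converged(ranks):
        return None
    final = run_gr(normX, members)
    return GeneCluster(
        cluster_id="",
        seed_gene=seed_gene,
        members=frozenset(members),
        loocv_ranks=ranks,
        selected_experiments=final.selected_experiments,
    )


def find_all_clusters(
    normX: ExpressionMatrix, cfg: SearchConfig | None = None
) -> list[GeneCluster]:
    """Try every gene as a seed; deduplicate identical member sets (first
    seed wins) and drop clusters nested inside a larger retained cluster."""
    cfg = cfg or SearchConfig()
    found: list[GeneCluster] = []
    seen: set[frozenset[str]] = set()
    for seed in normX.gene_ids:
        cluster = refine_cluster(normX, seed, cfg)
        if cluster is None or cluster.members in seen:
            continue
        seen.add(cluster.members)
        found.append(cluster)
    # subset absorption: drop clusters strictly contained in another
    kept: list[GeneCluster] = []
    for c in found:
        if any(c.members < other.members for other in found):
            continue
        kept.append(c)
    for i, c in enumerate(kept, start=1):
        c.cluster_id = f"C{i:04d}"
    logger.info("cluster search: %d clusters from %d seeds", len(kept), normX.n_genes)
    return kept


def write_clusters(clusters: list[GeneCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tseed_gene\tmembers\tloocv_ranks\n")
        for c in clusters:
            members = sorted(c.members)
            ranks = ",".join(str(c.loocv_ranks.get(m, "")) for m in members)
            fh.write(f"{c.cluster_id}\t{c.seed_gene}\t{','.join(members)}\t{ranks}\n")


def read_clusters(path) -> list[GeneCluster]:
    clusters = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["cluster_id", "seed_gene", "members"]:
            raise ValueError("unexpected cluster table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            members = f[2].split(",")
            ranks = {}
            if len(f) > 3 and f[3]:
                for m, r in zip(members, f[3].split(",")):
                    if r:
                        ranks[m] = int(r)
            clusters.append(GeneCluster(
                cluster_id=f[0], seed_gene=f[1],
                members=frozenset(members), loocv_ranks=ranks,
            ))
    return clusters
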