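import numpy as np
import pytest
import scipy.stats

from crequtl.annotate_enrich import (
    GeneQ,
    assign_gene_q,
    classify_snp_position,
    ks_enrichment,
    ld_prune,
    pairwise_r2,
    run_go_enrichment,
)
from crequtl.data_io import (
    AssociationResult,
    GeneAnnotation,
    GOTable,
    SnpLocus,
)
from tests.conftest import make_genotypes


def _assoc(snp_id, q, chrom="chr1", pos=100, cluster="C0001"):
    return AssociationResult(
        cluster_id=cluster, snp_id=snp_id, chrom=chrom, pos=pos,
        member_genes=("A", "B", "C"), group_sizes=(20, 20),
        bartlett_stat=5.0, p=q / 2, q=q,
    )


class TestPairwiseR2:
    def test_identical_vectors(self):
        codes = np.tile(np.array([[0, 1, 2, 0, 1, 2]]), (2, 1))
        G = make_genotypes(codes)
        r2 = pairwise_r2(G, G.snp_ids)
        assert r2[0, 1] == pytest.approx(1.0)

    def test_printed_toy_pair(self):
        codes = np.array([[0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 1]])
        G = make_genotypes(codes)
        r2 = pairwise_r2(G, G.snp_ids)
        r = np.corrcoef(codes[0], codes[1])[0, 1]
        assert r2[0, 1] == pytest.approx(r * r)
        assert r2[0, 1] == pytest.approx(0.80, abs=0.01)

    def test_independent_snps_low_r2(self, rng):
        codes = rng.binomial(2, 0.4, size=(2, 1000)).astype(np.int8)
        G = make_genotypes(codes)
        assert pairwise_r2(G, G.snp_ids)[0, 1] < 0.01

    def test_monomorphic_flagged_nan(self):
        codes = np.array([[0, 0, 0, 0], [0, 1, 2, 1]])
        G = make_genotypes(codes)
        assert np.isnan(pairwise_r2(G, G.snp_ids)[0, 1])


class TestLdPrune:
    def _high_ld_block(self, rng, n_samples=60):
        base = rng.binomial(2, 0.4, size=n_samples).astype(np.int8)
        codes = np.tile(base, (5, 1))
        for i in range(1, 5):  # a single discordant call keeps r2 ~ 0.95
            j = rng.integers(n_samples)
            codes[i, j] = (codes[i, j] + 1) % 3
        return make_genotypes(codes)

    def test_block_collapses_to_best_q(self, rng):
        G = self._high_ld_block(rng)
        results = [_assoc(f"rs{i + 1}", q=0.001 * (i + 1)) for i in range(5)]
        kept = ld_prune(results, G, r2_max=0.5)
        assert {r.snp_id for r in kept} == {"rs1"}  # smallest q
        assert all(r.pruned for r in results if r.snp_id != "rs1")

    def test_uncorrelated_identity(self, rng):
        codes = rng.binomial(2, 0.4, size=(4, 500)).astype(np.int8)
        G = make_genotypes(codes)
        results = [_assoc(f"rs{i + 1}", q=0.01 * (i + 1)) for i in range(4)]
        kept = ld_prune(results, G, r2_max=0.5)
        assert len(kept) == 4

    def test_row_order_invariance(self, rng):
        G = self._high_ld_block(rng)
        results = [_assoc(f"rs{i + 1}", q=0.001 * (5 - i)) for i in range(5)]
        k1 = {r.snp_id for r in ld_prune(list(results), G)}
        k2 = {r.snp_id for r in ld_prune(list(results[::-1]), G)}
        assert k1 == k2

    def test_output_max_r2_bounded(self, rng):
        codes = rng.binomial(2, 0.4, size=(12, 80)).astype(np.int8)
        codes[6:] = codes[:6]  # duplicated block
        G = make_genotypes(codes)
        results = [_assoc(f"rs{i + 1}", q=0.001 * (i + 1)) for i in range(12)]
        kept = ld_prune(results, G, r2_max=0.5)
        snps = sorted({r.snp_id for r in kept})
        if len(snps) >= 2:
            r2 = pairwise_r2(G, snps)
            off = r2[~np.eye(len(snps), dtype=bool)]
            assert np.nanmax(off) <= 0.5


GENE_PLUS = GeneAnnotation(
    "GENEA", "chr1", "+", tx_start=10_000, tx_end=20_000,
    cds_start=12_000, cds_end=18_000,
    exons=[(10_000, 13_000), (15_000, 16_000), (17_500, 20_000)],
)
GENE_MINUS = GeneAnnotation(
    "GENEB", "chr1", "-", tx_start=50_000, tx_end=60_000,
    cds_start=52_000, cds_end=58_000, exons=[(50_000, 60_000)],
)


class TestClassifySnpPosition:
    def test_intron_inside_host_gene(self):
        sp = classify_snp_position(SnpLocus("chr1", 14_000), [GENE_PLUS])
        assert (sp.klass, sp.distance_bp, sp.nearest_gene) == ("intron", 0, "GENEA")

    def test_coding_position(self):
        sp = classify_snp_position(SnpLocus("chr1", 12_500), [GENE_PLUS])
        assert sp.klass == "coding"

    def test_utr5_and_utr3_by_strand(self):
        plus5 = classify_snp_position(SnpLocus("chr1", 11_000), [GENE_PLUS])
        plus3 = classify_snp_position(SnpLocus("chr1", 19_000), [GENE_PLUS])
        assert (plus5.klass, plus3.klass) == ("utr5", "utr3")
        minus5 = classify_snp_position(SnpLocus("chr1", 59_000), [GENE_MINUS])
        minus3 = classify_snp_position(SnpLocus("chr1", 51_000), [GENE_MINUS])
        assert (minus5.klass, minus3.klass) == ("utr5", "utr3")

    def test_upstream_distance(self):
        # 183,849 bp 5' of a +-strand transcript start
        gene = GeneAnnotation("STARDLIKE", "chr13", "+",
                              tx_start=1_000_000, tx_end=1_050_000)
        sp = classify_snp_position(SnpLocus("chr13", 1_000_000 - 183_849), [gene])
        assert (sp.klass, sp.distance_bp) == ("upstream", 183_849)

    def test_downstream_for_minus_strand(self):
        sp = classify_snp_position(SnpLocus("chr1", 45_000), [GENE_MINUS])
        assert sp.klass == "downstream"

    def test_equidistant_tie_lexicographic(self):
        a = GeneAnnotation("AAA", "chr1", "+", 1_000, 2_000)
        b = GeneAnnotation("BBB", "chr1", "+", 4_000, 5_000)
        sp = classify_snp_position(SnpLocus("chr1", 3_000), [a, b])
        assert sp.nearest_gene == "AAA"

    def test_far_snp_intergenic(self):
        sp = classify_snp_position(
            SnpLocus("chr1", 90_000_000), [GENE_PLUS], max_dist=5_000_000
        )
        assert sp.klass == "intergenic_far"

    def test_mirror_symmetry(self):
        """Mirroring coordinates and flipping strand preserves the class."""
        L = 100_000
        gene_m = GeneAnnotation("GENEA", "chr1", "-",
                                tx_start=L - 20_000, tx_end=L - 10_000)
        for pos in (5_000, 25_000):
            orig = classify_snp_position(
                SnpLocus("chr1", pos),
                [GeneAnnotation("GENEA", "chr1", "+", 10_000, 20_000)],
            )
            mirrored = classify_snp_position(SnpLocus("chr1", L - pos), [gene_m])
            assert orig.klass == mirrored.klass
            assert orig.distance_bp == mirrored.distance_bp


class TestAssignGeneQ:
    def test_minimum_over_snps(self):
        gene = GeneAnnotation("GENEA", "chr1", "+", 1_000_000, 1_010_000)
        results = [
            _assoc("rs1", 0.3, pos=900_000),
            _assoc("rs2", 0.01, pos=1_200_000),
            _assoc("rs3", 0.5, pos=1_005_000),
        ]
        (gq,) = assign_gene_q(results, [gene])
        assert gq.q_min == pytest.approx(0.01)
        assert gq.n_snps_assigned == 3

    def test_window_boundary_inclusive(self):
        gene = GeneAnnotation("GENEA", "chr1", "+", 10_000_000, 10_001_000)
        at_edge = _assoc("rs1", 0.2, pos=10_000_000 - 5_000_000)
        outside = _assoc("rs2", 0.1, pos=10_000_000 - 5_000_001)
        (gq,) = assign_gene_q([at_edge, outside], [gene])
        assert gq.q_min == pytest.approx(0.2)
        assert gq.n_snps_assigned == 1

    def test_brute_force_oracle(self, rng):
        genes = [
            GeneAnnotation(f"G{i:02d}", f"chr{1 + i % 2}", "+",
                           int(s), int(s) + 10_000)
            for i, s in enumerate(rng.integers(1, 50_000_000, size=20))
        ]
        results = [
            _assoc(f"rs{i}", q=float(q), chrom=f"chr{1 + i % 2}",
                   pos=int(pos))
            for i, (q, pos) in enumerate(
                zip(rng.uniform(size=100), rng.integers(1, 50_000_000, size=100))
            )
        ]
        got = {g.gene_id: g.q_min for g in assign_gene_q(results, genes)}
        expected = {}
        for gene in genes:
            qs = []
            for r in results:
                if r.chrom != gene.chrom:
                    continue
                d = max(gene.tx_start - r.pos, r.pos - gene.tx_end, 0)
                if d <= 5_000_000:
                    qs.append(r.q)
            if qs:
                expected[gene.gene_id] = min(qs)
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k])


class TestKsEnrichment:
    def _gene_q(self, qvals):
        return [GeneQ(f"g{i}", float(q), 1) for i, q in enumerate(qvals)]

    def test_whole_universe_degenerate(self, rng):
        gq = self._gene_q(rng.uniform(size=50))
        res = ks_enrichment(gq, {g.gene_id for g in gq}, B=100, rng_seed=0)
        assert res.p_perm == 1.0

    def test_smallest_qs_strongly_enriched(self, rng):
        qvals = rng.uniform(size=1000)
        order = np.argsort(qvals)
        category = {f"g{i}" for i in order[:10]}
        res = ks_enrichment(self._gene_q(qvals), category, B=10_000, rng_seed=1)
        assert res.p_perm <= 0.001

    def test_seeded_determinism(self, rng):
        qvals = rng.uniform(size=200)
        cat = {f"g{i}" for i in range(15)}
        r1 = ks_enrichment(self._gene_q(qvals), cat, B=500, rng_seed=99)
        r2 = ks_enrichment(self._gene_q(qvals), cat, B=500, rng_seed=99)
        assert r1.p_perm == r2.p_perm and r1.ks_stat == r2.ks_stat

    def test_below_floor_skipped(self, rng):
        gq = self._gene_q(rng.uniform(size=100))
        assert ks_enrichment(gq, {"g0", "g1"}, B=100, rng_seed=0) is None

    def test_observed_stat_matches_scipy_one_sided(self, rng):
        qvals = rng.uniform(size=300)  # continuous, tie-free
        cat_ids = {f"g{i}" for i in range(40)}
        res = ks_enrichment(self._gene_q(qvals), cat_ids, B=10, rng_seed=0)
        cat = qvals[:40]
        rest = qvals[40:]
        ref = scipy.stats.ks_2samp(cat, rest, alternative="greater")
        assert res.ks_stat == pytest.approx(ref.statistic, abs=1e-12)


class TestRunGoEnrichment:
    def test_empty_when_no_category_qualifies(self, rng):
        gq = [GeneQ(f"g{i}", float(q), 1) for i, q in enumerate(rng.uniform(size=30))]
        go = GOTable({"GO:1": ("BP", frozenset({"g0", "g1"}))})
        assert run_go_enrichment(gq, go, B=100, seed=0) == []

    def test_planted_category_ranks_first(self, rng):
        qvals = rng.uniform(0.2, 1.0, size=400)
        qvals[:15] = rng.uniform(0.0, 0.01, size=15)  # planted signal
        gq = [GeneQ(f"g{i}", float(q), 1) for i, q in enumerate(qvals)]
        cats = {"GO:signal": ("BP", frozenset(f"g{i}" for i in range(15)))}
        for c in range(10):
            members = frozenset(
                f"g{i}" for i in rng.choice(400, size=20, replace=False)
            )
            cats[f"GO:null{c}"] = ("MF", members)
        results = run_go_enrichment(gq, GOTable(cats), B=1000, seed=3)
        assert results[0].category_id == "GO:signal"

    def test_category_order_invariance(self, rng):
        qvals = rng.uniform(size=200)
        gq = [GeneQ(f"g{i}", float(q), 1) for i, q in enumerate(qvals)]
        cats = {
            f"GO:{c}": ("BP", frozenset(
                f"g{i}" for i in rng.choice(200, size=15, replace=False)
            ))
            for c in "abcd"
        }
        r1 = run_go_enrichment(gq, GOTable(cats), B=300, seed=5)
        reordered = GOTable(dict(reversed(list(cats.items()))))
        r2 = run_go_enrichment(gq, reordered, B=300, seed=5)
        assert [(r.category_id, r.p_perm, r.q) for r in r1] == [
            (r.category_id, r.p_perm, r.q) for r in r2
        ]
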