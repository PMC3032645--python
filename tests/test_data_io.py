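import numpy as np
import pytest

from crequtl import data_io
from crequtl.data_io import (
    MISSING,
    AssociationResult,
    ExpressionMatrix,
    GeneAnnotation,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestExpressionIO:
    def test_basic_parse(self, tmp_path):
        p = _write(tmp_path / "x.tsv",
                   "gene_id\tS1\tS2\tS3\nG1\t1.0\t2.0\t3.0\nG2\t4\t5\t6\n")
        X = data_io.read_expression(p)
        assert X.gene_ids == ["G1", "G2"]
        assert X.sample_ids == ["S1", "S2", "S3"]
        assert X.values.shape == (2, 3)
        np.testing.assert_allclose(X.values[1], [4, 5, 6])

    def test_duplicate_gene_rejected(self, tmp_path):
        p = _write(tmp_path / "x.tsv",
                   "gene_id\tS1\tS2\nG1\t1\t2\nG1\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate gene id G1"):
            data_io.read_expression(p)

    def test_non_numeric_cell_named(self, tmp_path):
        p = _write(tmp_path / "x.tsv",
                   "gene_id\tS1\tS2\nG1\t1\tfoo\n")
        with pytest.raises(ValueError, match="G1.*S2"):
            data_io.read_expression(p)

    def test_round_trip_identity(self, tmp_path, rng):
        X = ExpressionMatrix(
            [f"G{i}" for i in range(10)],
            [f"S{j}" for j in range(5)],
            rng.normal(size=(10, 5)),
        )
        data_io.write_expression(X, tmp_path / "x.tsv")
        X2 = data_io.read_expression(tmp_path / "x.tsv")
        assert X2.gene_ids == X.gene_ids and X2.sample_ids == X.sample_ids
        np.testing.assert_array_equal(X2.values, X.values)


class TestGenotypeIO:
    def test_tsv_parse_and_missing(self, tmp_path):
        p = _write(tmp_path / "g.tsv",
                   "snp_id\tchrom\tpos\tS1\tS2\nrs1\tchr1\t100\t0\tNA\nrs2\tchr2\t5\t2\t1\n")
        G = data_io.read_genotypes(p, dialect="tsv")
        assert G.codes[0, 1] == MISSING
        assert G.codes[1, 0] == 2
        assert G.loci[1].chrom == "chr2" and G.loci[1].pos == 5

    def test_invalid_code_rejected(self, tmp_path):
        p = _write(tmp_path / "g.tsv",
                   "snp_id\tchrom\tpos\tS1\nrs1\tchr1\t100\t3\n")
        with pytest.raises(ValueError, match="invalid genotype code"):
            data_io.read_genotypes(p, dialect="tsv")

    def test_vcf_gt_mapping(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\n"
            "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
        )
        p = _write(tmp_path / "g.vcf", vcf)
        G = data_io.read_genotypes(p, dialect="vcf")
        assert list(G.codes[0]) == [0, 1, 2, MISSING]

    def test_vcf_multiallelic_skipped(self, tmp_path, caplog):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        body = "".join(
            f"chr1\t{100 + i}\trs{i}\tA\tG\t.\tPASS\t.\tGT\t0/1\n" for i in range(9)
        )
        tri = "chr1\t500\trsX\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n"
        p = _write(tmp_path / "g.vcf", header + body + tri)
        with caplog.at_level("WARNING"):
            G = data_io.read_genotypes(p, dialect="vcf")
        assert G.n_snps == 9
        assert any("multi-allelic" in r.message for r in caplog.records)

    def test_tsv_round_trip(self, tmp_path, rng):
        codes = rng.integers(0, 3, size=(6, 4)).astype(np.int8)
        codes[0, 0] = MISSING
        from tests.conftest import make_genotypes

        G = make_genotypes(codes)
        data_io.write_genotypes_tsv(G, tmp_path / "g.tsv")
        G2 = data_io.read_genotypes(tmp_path / "g.tsv", dialect="tsv")
        np.testing.assert_array_equal(G2.codes, G.codes)
        assert G2.snp_ids == G.snp_ids


class TestAnnotationIO:
    BED = ("chr1\t99\t500\tGENE1\t0\t+\t150\t400\t0\t3\t51,100,100\t0,150,301\n"
           "chr1\t10\t80\tGENE0\t0\t-\t10\t10\t0\t1\t70\t0\n")

    def test_bed12_coordinate_conversion(self, tmp_path):
        p = _write(tmp_path / "a.bed", self.BED)
        genes = data_io.read_gene_annotation(p, dialect="bed12")
        g1 = [g for g in genes if g.gene_id == "GENE1"][0]
        assert g1.tx_start == 100 and g1.tx_end == 500
        assert g1.cds_start == 151 and g1.cds_end == 400
        assert g1.exons == [(100, 150), (250, 349), (401, 500)]
        g0 = [g for g in genes if g.gene_id == "GENE0"][0]
        assert g0.cds_start is None  # thickStart == thickEnd -> noncoding

    def test_sorted_output(self, tmp_path):
        lines = [
            f"chr1\t{s}\t{s + 50}\tG{s}\t0\t+\t{s}\t{s}\t0\t1\t50\t0\n"
            for s in (400, 100, 300, 200, 500)
        ]
        p = _write(tmp_path / "a.bed", "".join(lines))
        genes = data_io.read_gene_annotation(p, dialect="bed12")
        starts = [g.tx_start for g in genes]
        assert starts == sorted(starts)

    def test_bed_round_trip_involutive(self, tmp_path):
        p = _write(tmp_path / "a.bed", self.BED)
        genes = data_io.read_gene_annotation(p, dialect="bed12")
        data_io.write_bed12(genes, tmp_path / "b.bed")
        genes2 = data_io.read_gene_annotation(tmp_path / "b.bed", dialect="bed12")
        assert genes == genes2

    def test_gff3_minimal(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr2\t.\tgene\t1000\t2000\t.\t+\t.\tID=GA\n"
            "chr2\t.\texon\t1000\t1200\t.\t+\t.\tParent=GA\n"
            "chr2\t.\texon\t1500\t2000\t.\t+\t.\tParent=GA\n"
            "chr2\t.\tCDS\t1100\t1700\t.\t+\t0\tParent=GA\n"
        )
        p = _write(tmp_path / "a.gff3", gff)
        (g,) = data_io.read_gene_annotation(p, dialect="gff3-minimal")
        assert (g.tx_start, g.tx_end) == (1000, 2000)
        assert (g.cds_start, g.cds_end) == (1100, 1700)
        assert len(g.exons) == 2

    def test_exon_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside transcript"):
            GeneAnnotation("g", "chr1", "+", 100, 200, exons=[(50, 150)])

    def test_three_exons_imply_two_introns(self, tmp_path):
        p = _write(tmp_path / "a.bed", self.BED)
        genes = data_io.read_gene_annotation(p, dialect="bed12")
        g1 = [g for g in genes if g.gene_id == "GENE1"][0]
        introns = [
            (g1.exons[i][1] + 1, g1.exons[i + 1][0] - 1)
            for i in range(len(g1.exons) - 1)
        ]
        assert introns == [(151, 249), (350, 400)]


def _assoc(cluster, snp, q, p=None):
    return AssociationResult(
        cluster_id=cluster, snp_id=snp, chrom="chr1", pos=100,
        member_genes=("A", "B", "C"), group_sizes=(10, 10),
        bartlett_stat=1.0, p=p if p is not None else q, q=q,
    )


class TestAssociationIO:
    def test_empty_results_header_only(self, tmp_path):
        data_io.write_associations([], tmp_path / "a.tsv")
        lines = (tmp_path / "a.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("cluster_id\t")

    def test_sorted_by_q(self, tmp_path):
        rows = [_assoc("C1", "rs1", 0.01), _assoc("C1", "rs2", 0.001)]
        data_io.write_associations(rows, tmp_path / "a.tsv")
        lines = (tmp_path / "a.tsv").read_text().splitlines()
        assert "rs2" in lines[1] and "rs1" in lines[2]

    def test_round_trip(self, tmp_path):
        rows = [_assoc(f"C{i}", f"rs{i}", q=0.01 * (i + 1), p=0.001 * (i + 1))
                for i in range(5)]
        data_io.write_associations(rows, tmp_path / "a.tsv")
        back = data_io.read_associations(tmp_path / "a.tsv")
        assert len(back) == 5
        for orig, rt in zip(sorted(rows, key=lambda r: r.q), back):
            assert rt.cluster_id == orig.cluster_id
            assert rt.snp_id == orig.snp_id
            assert rt.member_genes == orig.member_genes
            assert rt.p == orig.p and rt.q == orig.q


class TestGOTableIO:
    def test_round_trip(self, tmp_path):
        from crequtl.data_io import GOTable

        go = GOTable({
            "GO:1": ("BP", frozenset({"g1", "g2"})),
            "GO:2": ("MF", frozenset({"g3"})),
        })
        data_io.write_go_table(go, tmp_path / "go.tsv")
        back = data_io.read_go_table(tmp_path / "go.tsv")
        assert back.categories == go.categories

    def test_bad_namespace_rejected(self):
        from crequtl.data_io import GOTable

        with pytest.raises(ValueError, match="namespace"):
            GOTable({"GO:1": ("XX", frozenset({"g"}))})
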