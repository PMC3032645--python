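"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the in-memory domain types defined
here.  Internal coordinates are 1-based inclusive everywhere; the readers
own all dialect arithmetic (BED's 0-based half-open intervals are converted
on the way in and back on the way out).  Missing genotype calls are coded
with the dedicated sentinel :data:`MISSING`, distinct from any valid code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call (valid codes are 0, 1, 2).
MISSING: int = -1

VALID_CODES = (0, 1, 2)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression with unique IDs and no NaNs."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        lookup = self._gene_lookup()
        try:
            return lookup[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def _gene_lookup(self) -> dict[str, int]:
        # cached; gene_ids are immutable by convention after construction
        cache = getattr(self, "_gene_index_cache", None)
        if cache is None or len(cache) != len(self.gene_ids):
            cache = {g: i for i, g in enumerate(self.gene_ids)}
            self._gene_index_cache = cache
        return cache

    def _lex_rank(self) -> np.ndarray:
        """Rank of each gene id in lexicographic order (cached); used as a
        deterministic, row-order-independent tie-break in rankings."""
        cache = getattr(self, "_lex_rank_cache", None)
        if cache is None or len(cache) != len(self.gene_ids):
            order = np.argsort(np.asarray(self.gene_ids, dtype=object))
            cache = np.empty(len(self.gene_ids), dtype=int)
            cache[order] = np.arange(len(self.gene_ids))
            self._lex_rank_cache = cache
        return cache

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            values=self.values[keep],
        )


@dataclass
class SnpLocus:
    chrom: str
    pos: int  # 1-based
    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """SNPs x samples genotype codes in {0,1,2,MISSING} with optional
    per-call confidences and per-SNP loci."""

    snp_ids: list[str]
    sample_ids: list[str]
    codes: np.ndarray
    confidences: np.ndarray | None = None
    loci: list[SnpLocus] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("genotype code shape does not match IDs")
        _check_unique(self.snp_ids, "SNP")
        _check_unique(self.sample_ids, "sample")
        bad = ~np.isin(self.codes, VALID_CODES + (MISSING,))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} at SNP "
                f"{self.snp_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.confidences is not None:
            self.confidences = np.asarray(self.confidences, dtype=float)
            if self.confidences.shape != self.codes.shape:
                raise ValueError("confidence shape differs from code shape")
        if self.loci is not None and len(self.loci) != len(self.snp_ids):
            raise ValueError("loci length differs from SNP count")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            snp_ids=[self.snp_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            codes=self.codes[keep],
            confidences=None if self.confidences is None else self.confidences[keep],
            loci=None if self.loci is None else [self.loci[i] for i in keep],
        )


@dataclass
class GeneAnnotation:
    """One gene's transcript structure in 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None = None
    cds_end: int | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start > tx_end")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript bounds")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e


@dataclass
class GOTable:
    """Gene Ontology membership: category -> namespace + member genes."""

    categories: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for cat, (ns, members) in self.categories.items():
            if ns not in ("BP", "CC", "MF"):
                raise ValueError(f"category {cat}: namespace {ns!r} not in BP/CC/MF")
            if not members:
                raise ValueError(f"category {cat}: empty member set")


@dataclass
class AssociationResult:
    """One (cluster, SNP) variance-heterogeneity test result."""

    cluster_id: str
    snp_id: str
    chrom: str
    pos: int
    member_genes: tuple[str, ...]
    group_sizes: tuple[int, ...]
    bartlett_stat: float
    p: float
    q: float
    pruned: bool = False
    nearest_gene: str = ""


# ---------------------------------------------------------------------------
# Expression I/O
# ---------------------------------------------------------------------------

def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples TSV (header row = sample IDs, first column =
    gene IDs) into an :class:`ExpressionMatrix`.

    Duplicate IDs and non-numeric or missing cells are rejected with an
    error naming the offending entry.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown expression dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    for ids, kind in ((genes, "gene"), (samples, "sample")):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise ValueError(f"duplicate {kind} id {x}")
            seen.add(x)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                raise ValueError(f"missing cell at gene {genes[i]}, sample {samples[j]}")
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at gene {genes[i]}, sample {samples[j]}"
                ) from None
    return ExpressionMatrix(genes, samples, values)


def write_expression(X: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read genotypes from a TSV (snp_id, chrom, pos, then one column per
    sample; ``NA`` = missing call) or from a VCF 4.x file.

    VCF GT fields map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2 and ./. to the
    missing sentinel; multi-allelic records are skipped with a warning.
    A GQ FORMAT field, when present, becomes a per-call confidence in
    [0, 1] via the Phred convention 1 - 10^(-GQ/10).
    """
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["snp_id", "chrom", "pos"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"genotype TSV must start with columns {expected}")
    sample_ids = [str(s) for s in df.columns[3:]]
    snp_ids = [str(s) for s in df["snp_id"]]
    loci = [SnpLocus(str(c), int(p)) for c, p in zip(df["chrom"], df["pos"])]
    codes = np.empty((len(snp_ids), len(sample_ids)), dtype=np.int8)
    for j, col in enumerate(df.columns[3:]):
        for i, cell in enumerate(df[col]):
            if cell in ("NA", ".", "", None) or (
                isinstance(cell, float) and math.isnan(cell)
            ):
                codes[i, j] = MISSING
                continue
            try:
                v = int(cell)
            except (TypeError, ValueError):
                v = -999
            if v not in VALID_CODES:
                raise ValueError(
                    f"invalid genotype code {cell!r} at SNP {snp_ids[i]}, "
                    f"sample {sample_ids[j]}"
                )
            codes[i, j] = v
    return GenotypeMatrix(snp_ids, sample_ids, codes, loci=loci)


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    loci: list[SnpLocus] = []
    code_rows: list[np.ndarray] = []
    conf_rows: list[np.ndarray] = []
    any_gq = False
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping multi-allelic record %s:%d (%d ALT alleles)",
                var.CHROM, var.POS, len(var.ALT),
            )
            continue
        gts = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2; 3 = missing
        if gts.size != len(sample_ids):
            raise ValueError("VCF record without GT field")
        row = np.where(gts == 3, MISSING, gts).astype(np.int8)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(snp_id)
        alt = var.ALT[0]
        loci.append(SnpLocus(var.CHROM, var.POS, (var.REF, alt)))
        code_rows.append(row)
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            any_gq = True
            gq = np.asarray(gq, dtype=float).reshape(-1)
            conf_rows.append(1.0 - np.power(10.0, -np.clip(gq, 0, None) / 10.0))
        else:
            conf_rows.append(np.full(len(sample_ids), np.nan))
    if not snp_ids:
        raise ValueError(f"no usable biallelic records in {path}")
    if n_skipped:
        logger.warning("skipped %d multi-allelic records", n_skipped)
    codes = np.vstack(code_rows)
    confidences = np.vstack(conf_rows) if any_gq else None
    if confidences is not None:
        confidences = np.where(np.isnan(confidences), 1.0, confidences)
    return GenotypeMatrix(snp_ids, sample_ids, codes, confidences, loci)


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    if G.loci is None:
        raise ValueError("cannot write genotype TSV without loci")
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\t" + "\t".join(G.sample_ids) + "\n")
        for i, sid in enumerate(G.snp_ids):
            loc = G.loci[i]
            cells = ["NA" if c == MISSING else str(int(c)) for c in G.codes[i]]
            fh.write(f"{sid}\t{loc.chrom}\t{loc.pos}\t" + "\t".join(cells) + "\n")


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal uncompressed VCF 4.2 with GT calls."""
    if G.loci is None:
        raise ValueError("cannot write VCF without loci")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    order = sorted(range(G.n_snps), key=lambda i: (G.loci[i].chrom, G.loci[i].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({loc.chrom for loc in G.loci}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids) + "\n"
        )
        for i in order:
            loc = G.loci[i]
            ref, alt = loc.alleles if loc.alleles else ("A", "G")
            calls = "\t".join(gt_map[int(c)] for c in G.codes[i])
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{G.snp_ids[i]}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation I/O
# ---------------------------------------------------------------------------

def read_gene_annotation(path, dialect: str = "bed12") -> list[GeneAnnotation]:
    """Read gene models from BED12 (0-based half-open, converted to 1-based
    inclusive) or minimal GFF3 (gene/exon/CDS features, already 1-based).

    The result is sorted by (chrom, tx_start, gene_id).
    """
    if dialect == "bed12":
        genes = _read_bed12(path)
    elif dialect == "gff3-minimal":
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return genes


def _read_bed12(path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 line has {len(f)} fields: {line!r}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(f"BED12 block counts inconsistent for {name}")
            exons = [
                (start + bs + 1, start + bs + sz)  # 0-based half-open -> 1-based incl.
                for bs, sz in zip(starts, sizes)
            ]
            cds_start = cds_end = None
            if thick_end > thick_start:
                cds_start, cds_end = thick_start + 1, thick_end
            genes.append(GeneAnnotation(
                gene_id=name, chrom=chrom, strand=strand,
                tx_start=start + 1, tx_end=end,
                cds_start=cds_start, cds_end=cds_end, exons=exons,
            ))
    return genes


def write_bed12(genes: list[GeneAnnotation], path) -> None:
    """Inverse of :func:`_read_bed12` (1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            start0 = g.tx_start - 1
            exons = g.exons or [(g.tx_start, g.tx_end)]
            sizes = ",".join(str(e - s + 1) for s, e in exons)
            starts = ",".join(str(s - 1 - start0) for s, _e in exons)
            if g.cds_start is not None:
                thick = (g.cds_start - 1, g.cds_end)
            else:
                thick = (start0, start0)
            fh.write("\t".join(map(str, [
                g.chrom, start0, g.tx_end, g.gene_id, 0, g.strand,
                thick[0], thick[1], "0", len(exons), sizes, starts,
            ])) + "\n")


def _read_gff3(path) -> list[GeneAnnotation]:
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    cds_rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"GFF3 line has {len(f)} fields: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ValueError(f"gene feature without ID: {line!r}")
                gene_rows[gid] = dict(
                    chrom=chrom, strand=strand, tx_start=int(start), tx_end=int(end)
                )
            elif ftype == "exon":
                exon_rows.setdefault(attr.get("Parent", ""), []).append(
                    (int(start), int(end))
                )
            elif ftype == "CDS":
                cds_rows.setdefault(attr.get("Parent", ""), []).append(
                    (int(start), int(end))
                )
    genes = []
    for gid, row in gene_rows.items():
        exons = sorted(exon_rows.get(gid, []))
        cds = cds_rows.get(gid)
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        if not exons:
            exons = [(row["tx_start"], row["tx_end"])]
        genes.append(GeneAnnotation(
            gene_id=gid, cds_start=cds_start, cds_end=cds_end, exons=exons, **row
        ))
    return genes


# ---------------------------------------------------------------------------
# GO table I/O
# ---------------------------------------------------------------------------

def read_go_table(path) -> GOTable:
    """Read a 3-column TSV (category_id, namespace, gene_id) into a GOTable."""
    members: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["category_id", "namespace", "gene_id"]:
            raise ValueError("GO table must have columns category_id/namespace/gene_id")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cat, ns, gene = line.split("\t")
            if cat in members and members[cat][0] != ns:
                raise ValueError(f"category {cat} listed under two namespaces")
            members.setdefault(cat, (ns, set()))[1].add(gene)
    return GOTable({c: (ns, frozenset(m)) for c, (ns, m) in members.items()})


def write_go_table(go: GOTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("category_id\tnamespace\tgene_id\n")
        for cat in sorted(go.categories):
            ns, members = go.categories[cat]
            for gene in sorted(members):
                fh.write(f"{cat}\t{ns}\t{gene}\n")


# ---------------------------------------------------------------------------
# Association table I/O
# ---------------------------------------------------------------------------

_ASSOC_COLUMNS = [
    "cluster_id", "member_genes", "snp_id", "chrom", "pos", "nearest_gene",
    "bartlett_stat", "p", "q", "pruned",
]


def write_associations(results: list[AssociationResult], path) -> None:
    """Write association results as TSV, ascending q then snp_id."""
    rows = sorted(results, key=lambda r: (r.q, r.snp_id))
    with open(path, "w") as fh:
        fh.write("\t".join(_ASSOC_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.cluster_id,
                ",".join(r.member_genes),
                r.snp_id,
                r.chrom,
                str(r.pos),
                r.nearest_gene,
                f"{r.bartlett_stat:.17g}",
                f"{r.p:.17g}",
                f"{r.q:.17g}",
                "1" if r.pruned else "0",
            ]) + "\n")


def read_associations(path) -> list[AssociationResult]:
    results = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ASSOC_COLUMNS:
            raise ValueError("unexpected association table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            results.append(AssociationResult(
                cluster_id=f[0],
                member_genes=tuple(f[1].split(",")) if f[1] else (),
                snp_id=f[2], chrom=f[3], pos=int(f[4]), nearest_gene=f[5],
                group_sizes=(),
                bartlett_stat=float(f[6]), p=float(f[7]), q=float(f[8]),
                pruned=f[9] == "1",
            ))
    return results


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id {x}")
        seen.add(x)
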