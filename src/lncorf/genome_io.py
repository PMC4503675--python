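"""Readers/writers for the standard genomic formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). VCF
positions (1-based) are converted at the boundary by :func:`from_vcf_pos`
and :func:`to_vcf_pos`.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .errors import FormatError

VALID_BASES = set("ACGTN")
REGION_CLASSES = ("CDS", "UTR", "exon", "intron", "intergenic_flank")
AGE_CLASS_RE = re.compile(r"^H(-[CGO])*$")

TABLE1_PATH = Path(__file__).parent / "data" / "table1.tsv"


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# Coordinate model
# ---------------------------------------------------------------------------

def from_vcf_pos(pos1: int) -> int:
    """Convert a 1-based VCF position to the internal 0-based model."""
    return pos1 - 1


def to_vcf_pos(pos0: int) -> int:
    """Convert an internal 0-based position to a 1-based VCF position."""
    return pos0 + 1


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open interval [start, end) on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end {self.end} must exceed start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end


@dataclass
class RegionAnnotation:
    """Per-gene mapping from region class to genomic intervals.

    ``frame_anchor`` is the genomic position of the first CDS base (codon
    position 1 in coding order; for minus-strand genes this is the highest
    CDS coordinate). Stored classes must be mutually non-overlapping;
    ``exon`` queries are answered from explicit exon intervals plus the
    union of CDS and UTR.
    """

    gene_id: str
    intervals: dict[str, list[GenomicInterval]]
    frame_anchor: int | None = None
    complete_orf: bool = True

    def __post_init__(self):
        for cls in self.intervals:
            if cls not in REGION_CLASSES:
                raise ValueError(f"unknown region class {cls!r}")
        if self.complete_orf and self.region_length("CDS") % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.region_length('CDS')} "
                "not divisible by 3 for a complete ORF"
            )
        self._check_disjoint()

    def _check_disjoint(self):
        by_contig: dict[str, list[tuple[int, int, str]]] = {}
        for cls, ivs in self.intervals.items():
            for iv in ivs:
                by_contig.setdefault(iv.contig, []).append((iv.start, iv.end, cls))
        for contig, spans in by_contig.items():
            spans.sort()
            for (s1, e1, c1), (s2, e2, c2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{self.gene_id}: overlapping intervals "
                        f"{c1}[{s1},{e1}) and {c2}[{s2},{e2}) on {contig}"
                    )

    def region_length(self, cls: str) -> int:
        if cls == "exon":
            return sum(
                len(iv)
                for c in ("exon", "CDS", "UTR")
                for iv in self.intervals.get(c, [])
            )
        return sum(len(iv) for iv in self.intervals.get(cls, []))

    def class_of(self, contig: str, pos: int) -> str | None:
        """Region class containing a 0-based position, or None."""
        for cls, ivs in self.intervals.items():
            for iv in ivs:
                if iv.contains(contig, pos):
                    return cls
        return None

    def cds_intervals(self) -> list[GenomicInterval]:
        """CDS intervals sorted in coding order (strand-aware)."""
        ivs = sorted(self.intervals.get("CDS", []), key=lambda iv: iv.start)
        if ivs and ivs[0].strand == "-":
            ivs = ivs[::-1]
        return ivs

    def cds_offset_of(self, contig: str, pos: int) -> int | None:
        """Offset of a genomic position within the spliced CDS, in coding
        order, or None if the position is not coding."""
        offset = 0
        for iv in self.cds_intervals():
            if iv.contains(contig, pos):
                if iv.strand == "-":
                    return offset + (iv.end - 1 - pos)
                return offset + (pos - iv.start)
            offset += len(iv)
        return None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered mapping id -> uppercased sequence.

    Only A, C, G, T and N are accepted; violations raise
    :class:`FormatError` naming the offending line.
    """
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    seen_record = False
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                header = line[1:].split()
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                name = header[0]
                if name in records:
                    raise FormatError(
                        f"{path}: duplicate FASTA id {name!r} at line {lineno}"
                    )
                chunks = []
                seen_record = True
            else:
                if not seen_record:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                seq = line.upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(seq)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str | None = None
    score: float | None = None


def read_bed(path) -> list[BedRecord]:
    """Read a 3-6 column BED file; coordinates kept 0-based half-open."""
    out: list[BedRecord] = []
    with _open_text(path) as fh:
        for idx, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: record {idx}: fewer than 3 columns")
            contig = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}: record {idx}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(
                    f"{path}: record {idx}: end {end} <= start {start}"
                )
            name = cols[3] if len(cols) > 3 else None
            score = None
            if len(cols) > 4 and cols[4] not in (".", ""):
                score = float(cols[4])
            strand = cols[5] if len(cols) > 5 else "+"
            out.append(
                BedRecord(GenomicInterval(contig, start, end, strand), name, score)
            )
    return out


def write_bed(records: Iterable[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            name = rec.name if rec.name is not None else "."
            score = rec.score if rec.score is not None else 0
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def annotation_from_bed(
    gene_id: str, records: Sequence[BedRecord], frame_anchor: int | None = None,
    complete_orf: bool = True,
) -> RegionAnnotation:
    """Build a RegionAnnotation from BED records whose name column is either
    a bare region class or ``gene_id|class``; records for other genes are
    ignored."""
    intervals: dict[str, list[GenomicInterval]] = {}
    for rec in records:
        if rec.name is None:
            continue
        if "|" in rec.name:
            gid, cls = rec.name.split("|", 1)
            if gid != gene_id:
                continue
        else:
            cls = rec.name
        if cls in REGION_CLASSES:
            intervals.setdefault(cls, []).append(rec.interval)
    ann = RegionAnnotation(gene_id, intervals, frame_anchor, complete_orf)
    if ann.frame_anchor is None and ann.intervals.get("CDS"):
        ivs = ann.cds_intervals()
        first = ivs[0]
        ann.frame_anchor = first.end - 1 if first.strand == "-" else first.start
    return ann


# ---------------------------------------------------------------------------
# Variants (VCF subset)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant in internal coordinates.

    ``genotypes`` holds one ``(a, b)`` pair per diploid sample, each allele
    0 (ref), 1 (alt) or None (missing / unrepresented multi-allelic allele).
    ``unpolarizable`` marks sites whose ancestral allele matches neither
    observed allele; they are flagged, never silently dropped.
    """

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    ancestral: str | None
    genotypes: tuple[tuple[int | None, int | None], ...]
    unpolarizable: bool = False

    @property
    def n_chromosomes(self) -> int:
        return sum(
            1 for g in self.genotypes for a in g if a is not None
        )

    @property
    def alt_count(self) -> int:
        return sum(1 for g in self.genotypes for a in g if a == 1)

    @property
    def derived_count(self) -> int | None:
        """Derived-allele count, polarized by the ancestral annotation."""
        if self.ancestral is None or self.unpolarizable:
            return None
        if self.ancestral == self.ref:
            return self.alt_count
        return sum(1 for g in self.genotypes for a in g if a == 0)


def read_variants(path) -> list[VariantRecord]:
    """Read a VCF(.gz) into biallelic :class:`VariantRecord` objects.

    Multi-allelic records are decomposed into one record per alternate
    allele; genotype calls carrying a different alternate allele become
    missing in the decomposed record. The ancestral allele is taken from
    the ``AA`` INFO field.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            raw_gts = []
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None or len(gt) != 2:
                    raise FormatError(
                        f"{path}: {rec.chrom}:{rec.pos}: genotype ploidy "
                        f"{0 if gt is None else len(gt)} != 2"
                    )
                raw_gts.append(gt)
            aa = rec.info.get("AA")
            if isinstance(aa, tuple):
                aa = aa[0]
            if aa is not None:
                aa = str(aa).upper()
            for k, alt in enumerate(alts, start=1):
                gts = tuple(
                    tuple(
                        None if a is None or a not in (0, k) else (1 if a == k else 0)
                        for a in gt
                    )
                    for gt in raw_gts
                )
                unpolar = aa is not None and aa not in (rec.ref, alt)
                out.append(
                    VariantRecord(
                        contig=rec.chrom,
                        pos=from_vcf_pos(rec.pos),
                        ref=rec.ref,
                        alt=alt,
                        ancestral=aa,
                        genotypes=gts,
                        unpolarizable=unpolar,
                    )
                )
    return out


def write_variants(records: Sequence[VariantRecord], path,
                   sample_names: Sequence[str] | None = None) -> None:
    """Write biallelic records as a minimal VCF v4.2 file."""
    records = list(records)
    n_samples = len(records[0].genotypes) if records else 0
    if sample_names is None:
        sample_names = [f"s{i}" for i in range(n_samples)]
    contigs = sorted({r.contig for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.contig, r.pos)):
            info = f"AA={rec.ancestral}" if rec.ancestral is not None else "."
            gts = "\t".join(
                "/".join("." if a is None else str(a) for a in g)
                for g in rec.genotypes
            )
            fh.write(
                f"{rec.contig}\t{to_vcf_pos(rec.pos)}\t.\t{rec.ref}\t{rec.alt}"
                f"\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Gene tables (Table-1-like TSV)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneTableRecord:
    gene_id: str
    age_class: str
    orf_length_codons: int
    top_tissue: str
    tissue_breadth: int
    peptide_count: int


def read_gene_table(path=TABLE1_PATH) -> list[GeneTableRecord]:
    """Read a gene-catalog TSV; defaults to the packaged 64-gene fixture.

    ``age_class`` must match ``H(-[CGO])*`` — the species-initial labels
    used for hominoid-specific genes (H human, C chimpanzee, G gorilla,
    O orangutan).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "gene_id", "age_class", "orf_length_codons",
        "top_tissue", "tissue_breadth", "peptide_count",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        if not AGE_CLASS_RE.match(row.age_class):
            raise FormatError(
                f"{path}: gene {row.gene_id}: bad age class {row.age_class!r}"
            )
        length = int(row.orf_length_codons)
        if length <= 0:
            raise FormatError(f"{path}: gene {row.gene_id}: non-positive ORF length")
        out.append(
            GeneTableRecord(
                gene_id=row.gene_id,
                age_class=row.age_class,
                orf_length_codons=length,
                top_tissue=row.top_tissue,
                tissue_breadth=int(row.tissue_breadth),
                peptide_count=int(row.peptide_count),
            )
        )
    return out
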