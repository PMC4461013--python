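"""Gene-model representation and GTF I/O.

Transcripts are ordered collections of exons in 5'->3' (transcript) order.
All internal coordinates are 0-based half-open; the GTF reader/writer
converts from/to the 1-based inclusive convention at the file boundary.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

from .errors import (
    EmptyAnnotationError,
    FormatError,
    InputError,
    OverlappingExonsError,
)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-annotated genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Exon:
    """One exon of a transcript; rank counts 1-based in 5'->3' order."""

    interval: GenomicInterval
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("exon rank must be >= 1")

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class Transcript:
    """One isoform: exons listed 5'->3' on the transcript strand.

    On the + strand transcript order equals ascending genomic order; on the
    - strand it is descending genomic order.  ``k`` (the exon count) drives
    all junction-count formulas: k-1 known junctions, (k-1)(k-2)/2 novel.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        ivs = sorted((e.interval for e in self.exons), key=lambda i: i.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise OverlappingExonsError(
                    f"transcript {self.id}: exons [{a.start},{a.end}) and "
                    f"[{b.start},{b.end}) overlap"
                )

    @property
    def k(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class AnnotationSet:
    """All transcripts of an annotation plus the gene-level groupings."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)

    def add(self, t: Transcript) -> None:
        if t.id in self.transcripts:
            raise FormatError(f"duplicate transcript id {t.id}")
        self.transcripts[t.id] = t
        self.genes.setdefault(t.gene_id, []).append(t.id)

    def gene_exon_union(self, gene_id: str) -> list[GenomicInterval]:
        """Merged exon intervals of every transcript of a gene.

        Used by the gene counter: a gene's footprint is the union of its
        exons across isoforms.
        """
        ivs = sorted(
            (e.interval for tid in self.genes[gene_id]
             for e in self.transcripts[tid].exons),
            key=lambda i: (i.start, i.end),
        )
        merged: list[GenomicInterval] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1].end and iv.chrom == merged[-1].chrom:
                last = merged[-1]
                if iv.end > last.end:
                    merged[-1] = GenomicInterval(
                        last.chrom, last.start, iv.end, last.strand
                    )
            else:
                merged.append(iv)
        return merged

    def __len__(self) -> int:
        return len(self.transcripts)


_ATTR_QUOTED = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_EQ = re.compile(r"(\w+)\s*=\s*\"?([^\";]+)\"?")


def _parse_attributes(text: str) -> dict[str, str]:
    """Accept both ``key "value";`` (Ensembl GTF) and ``key=value`` dialects."""
    attrs: dict[str, str] = {}
    for chunk in text.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = _ATTR_QUOTED.match(chunk) or _ATTR_EQ.match(chunk)
        if m:
            attrs[m.group(1)] = m.group(2).strip()
    return attrs


def read_gtf(path: str | os.PathLike) -> AnnotationSet:
    """Parse a GTF gene model into an :class:`AnnotationSet`.

    Only ``exon`` feature lines are used; 1-based inclusive coordinates are
    converted to 0-based half-open.  Exons are grouped per transcript and
    ranked 5'->3' on the transcript strand.
    """
    if not os.path.exists(path):
        raise InputError(f"GTF file not found: {path}")
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attr = fields[:9]
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr)
            if "transcript_id" not in attrs:
                raise FormatError(f"line {lineno}: exon without transcript_id")
            if "gene_id" not in attrs:
                raise FormatError(f"line {lineno}: exon without gene_id")
            tid = attrs["transcript_id"]
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            rec = per_tx.setdefault(
                tid, {"gene_id": attrs["gene_id"], "chrom": chrom,
                      "strand": strand, "intervals": []}
            )
            rec["intervals"].append(iv)
    if not per_tx:
        raise EmptyAnnotationError(f"no exon features in {path}")
    ann = AnnotationSet()
    for tid, rec in per_tx.items():
        ivs = sorted(rec["intervals"], key=lambda i: i.start,
                     reverse=(rec["strand"] == "-"))
        exons = [Exon(iv, rank) for rank, iv in enumerate(ivs, start=1)]
        ann.add(Transcript(tid, rec["gene_id"], rec["chrom"], rec["strand"], exons))
    return ann


def write_gtf(ann: AnnotationSet, path: str | os.PathLike) -> None:
    """Write exon lines back out in Ensembl GTF dialect (round-trip safe)."""
    with open(path, "w") as fh:
        for tid in sorted(ann.transcripts):
            t = ann.transcripts[tid]
            for e in t.exons:
                iv = e.interval
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                    f'exon_number "{e.rank}";'
                )
                fh.write(
                    f"{iv.chrom}\tsplicepipe\texon\t{iv.start + 1}\t{iv.end}\t."
                    f"\t{iv.strand}\t.\t{attrs}\n"
                )


def known_junctions(t: Transcript) -> list[tuple[int, int]]:
    """The k-1 (donor, acceptor) pairs joining consecutive exons.

    Pair i joins the 3' end of exon i to the 5' start of exon i+1 in
    transcript order.  Donor is the genomic position (0-based) of the exonic
    base 3'-adjacent to the intron, acceptor the first exonic base after it.
    """
    out = []
    for up, down in zip(t.exons, t.exons[1:]):
        out.append(donor_acceptor(up.interval, down.interval, t.strand))
    return out


def donor_acceptor(
    up: GenomicInterval, down: GenomicInterval, strand: str
) -> tuple[int, int]:
    """Genomic donor/acceptor positions of a junction from exon *up* to *down*
    (transcript order)."""
    if strand == "+":
        return up.end - 1, down.start
    return up.start, down.end - 1


def write_summary_tsv(ann: AnnotationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tchrom\tstrand\tk\n")
        for tid in sorted(ann.transcripts):
            t = ann.transcripts[tid]
            fh.write(f"{t.id}\t{t.gene_id}\t{t.chrom}\t{t.strand}\t{t.k}\n")
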