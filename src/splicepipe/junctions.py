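"""Splice-junction library construction.

Two junction categories exist: *known* junctions join adjacent exons of an
annotated transcript (k-1 per k-exon transcript); *novel* junctions arise by
exhaustively skipping one or more consecutive inner exons of a transcript
((k-1)(k-2)/2 per transcript).  Each junction record carries up to ``L``
bases of flanking exon sequence on each side, spliced together; a flanking
exon shorter than ``L`` contributes a truncated flank, which is why the
flank lengths are encoded in the record so the fusion point stays
recoverable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .annotation import AnnotationSet, GenomicInterval, Transcript, donor_acceptor
from .errors import FormatError
from .sequences import fetch, revcomp

DEFAULT_BOUNDARIES = (50, 75, 100, 150)

KNOWN = "known"
NOVEL = "novel"

JunctionKey = tuple[str, str, int, int]  # (chrom, strand, donor, acceptor)


@dataclass(frozen=True)
class Junction:
    """One (donor, acceptor) pair; identity is positional."""

    chrom: str
    strand: str
    donor: int
    acceptor: int
    category: str
    n_skipped: int

    def __post_init__(self) -> None:
        if (self.category == KNOWN) != (self.n_skipped == 0):
            raise ValueError("known junctions skip 0 exons, novel skip >= 1")

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.strand, self.donor, self.acceptor)


@dataclass
class JunctionRecord:
    """A junction plus its extracted flank sequence and provenance."""

    junction: Junction
    up_len: int
    down_len: int
    sequence: str
    source_transcripts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.sequence) != self.up_len + self.down_len:
            raise ValueError("sequence length must equal up_len + down_len")

    @property
    def record_id(self) -> str:
        j = self.junction
        return f"{j.chrom}:{j.strand}:{j.donor}:{j.acceptor}"

    @property
    def fusion_point(self) -> int:
        """Local 0-based position of the first downstream-flank base."""
        return self.up_len

    def flank_intervals(self) -> tuple[GenomicInterval, GenomicInterval]:
        """Genomic intervals of the two flanks (upstream first)."""
        j = self.junction
        if j.strand == "+":
            up = GenomicInterval(j.chrom, j.donor + 1 - self.up_len, j.donor + 1, "+")
            down = GenomicInterval(j.chrom, j.acceptor, j.acceptor + self.down_len, "+")
        else:
            up = GenomicInterval(j.chrom, j.donor, j.donor + self.up_len, "-")
            down = GenomicInterval(
                j.chrom, j.acceptor + 1 - self.down_len, j.acceptor + 1, "-"
            )
        return up, down


@dataclass
class JunctionLibrary:
    L: int
    records: dict[JunctionKey, JunctionRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, JunctionRecord]:
        return {r.record_id: r for r in self.records.values()}


def enumerate_known_junctions(t: Transcript) -> list[Junction]:
    out = []
    for up, down in zip(t.exons, t.exons[1:]):
        d, a = donor_acceptor(up.interval, down.interval, t.strand)
        out.append(Junction(t.chrom, t.strand, d, a, KNOWN, 0))
    return out


def enumerate_novel_junctions(t: Transcript) -> list[Junction]:
    """All exon-skipping junctions: exon i joined to exon j with j >= i+2.

    Every run of consecutive inner exons can be skipped, giving
    (k-1)(k-2)/2 junctions in total, of which the single-skip subset
    (j = i+2) has size k-2.
    """
    out = []
    k = t.k
    for i in range(k):
        for j in range(i + 2, k):
            d, a = donor_acceptor(t.exons[i].interval, t.exons[j].interval, t.strand)
            out.append(Junction(t.chrom, t.strand, d, a, NOVEL, j - i - 1))
    return out


def _flank_sequences(
    t: Transcript, i: int, j: int, genome, L: int
) -> tuple[int, int, str]:
    """Extract spliced flank sequence for the junction exon i -> exon j
    (transcript order), in transcript (sense) orientation."""
    up_iv = t.exons[i].interval
    down_iv = t.exons[j].interval
    up_len = min(L, len(up_iv))
    down_len = min(L, len(down_iv))
    if t.strand == "+":
        up_seq = fetch(genome, t.chrom, up_iv.end - up_len, up_iv.end)
        down_seq = fetch(genome, t.chrom, down_iv.start, down_iv.start + down_len)
    else:
        up_seq = revcomp(fetch(genome, t.chrom, up_iv.start, up_iv.start + up_len))
        down_seq = revcomp(fetch(genome, t.chrom, down_iv.end - down_len, down_iv.end))
    return up_len, down_len, up_seq + down_seq


def build_library(ann: AnnotationSet, genome, L: int = 75) -> JunctionLibrary:
    """Enumerate known + novel junctions of every transcript and extract flanks.

    Duplicate keys across transcripts merge into a single record; a key that
    is known in any transcript is categorized known even if it also arises
    as a skip elsewhere (known junctions are never double-counted as novel).
    """
    lib = JunctionLibrary(L=L)
    for tid, t in ann.transcripts.items():
        pairs = [(i, i + 1, KNOWN, 0) for i in range(t.k - 1)]
        pairs += [
            (i, j, NOVEL, j - i - 1)
            for i in range(t.k)
            for j in range(i + 2, t.k)
        ]
        for i, j, category, n_skipped in pairs:
            d, a = donor_acceptor(t.exons[i].interval, t.exons[j].interval, t.strand)
            junc = Junction(t.chrom, t.strand, d, a, category, n_skipped)
            existing = lib.records.get(junc.key)
            if existing is None:
                up_len, down_len, seq = _flank_sequences(t, i, j, genome, L)
                lib.records[junc.key] = JunctionRecord(
                    junc, up_len, down_len, seq, {tid}
                )
            else:
                existing.source_transcripts.add(tid)
                if category == KNOWN and existing.junction.category == NOVEL:
                    lib.records[junc.key] = JunctionRecord(
                        junc,
                        existing.up_len,
                        existing.down_len,
                        existing.sequence,
                        existing.source_transcripts,
                    )
    return lib


# --- FASTA round-trip -------------------------------------------------------

_HEADER_FIELDS = (
    "junction_id", "chrom", "strand", "donor", "acceptor",
    "up_len", "down_len", "category", "n_skipped",
)


def write_library_fasta(lib: JunctionLibrary, path: str | os.PathLike) -> None:
    """One entry per record; the header pipes together every junction field."""
    with open(path, "w") as fh:
        for key in sorted(lib.records):
            r = lib.records[key]
            j = r.junction
            header = "|".join(
                str(x)
                for x in (
                    r.record_id, j.chrom, j.strand, j.donor, j.acceptor,
                    r.up_len, r.down_len, j.category, j.n_skipped,
                )
            )
            fh.write(f">{header}\n{r.sequence}\n")


def read_library_fasta(path: str | os.PathLike) -> JunctionLibrary:
    """Reconstruct a library from the structured FASTA headers."""
    records: dict[JunctionKey, JunctionRecord] = {}
    L = 0
    with open(path) as fh:
        header = None
        seq_parts: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    rec = _record_from_header(header, "".join(seq_parts))
                    records[rec.junction.key] = rec
                    L = max(L, rec.up_len, rec.down_len)
                header = line[1:]
                seq_parts = []
            else:
                seq_parts.append(line)
        if header is not None:
            rec = _record_from_header(header, "".join(seq_parts))
            records[rec.junction.key] = rec
            L = max(L, rec.up_len, rec.down_len)
    return JunctionLibrary(L=L, records=records)


def _record_from_header(header: str, seq: str) -> JunctionRecord:
    parts = header.split("|")
    if len(parts) != len(_HEADER_FIELDS):
        raise FormatError(f"malformed junction FASTA header: {header}")
    _jid, chrom, strand, donor, acceptor, up_len, down_len, category, n_skipped = parts
    junc = Junction(chrom, strand, int(donor), int(acceptor), category, int(n_skipped))
    return JunctionRecord(junc, int(up_len), int(down_len), seq)


def write_manifest_tsv(lib: JunctionLibrary, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "junction_id\tchrom\tstrand\tdonor\tacceptor\tcategory\t"
            "n_skipped\tup_len\tdown_len\tn_source_transcripts\n"
        )
        for key in sorted(lib.records):
            r = lib.records[key]
            j = r.junction
            fh.write(
                f"{r.record_id}\t{j.chrom}\t{j.strand}\t{j.donor}\t{j.acceptor}\t"
                f"{j.category}\t{j.n_skipped}\t{r.up_len}\t{r.down_len}\t"
                f"{len(r.source_transcripts)}\n"
            )


def write_bed12(lib: JunctionLibrary, path: str | os.PathLike) -> None:
    """Browser track: one BED12 line per junction, one block per flank."""
    with open(path, "w") as fh:
        for key in sorted(lib.records):
            r = lib.records[key]
            up, down = r.flank_intervals()
            left, right = (up, down) if up.start <= down.start else (down, up)
            chrom_start = left.start
            chrom_end = right.end
            block_sizes = f"{len(left)},{len(right)}"
            block_starts = f"0,{right.start - chrom_start}"
            fh.write(
                f"{r.junction.chrom}\t{chrom_start}\t{chrom_end}\t{r.record_id}\t0\t"
                f"{r.junction.strand}\t{chrom_start}\t{chrom_end}\t0\t2\t"
                f"{block_sizes}\t{block_starts}\n"
            )
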