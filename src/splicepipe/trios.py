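"""Exon-trio database (TXdb) and cassette-exon inclusion ratios.

Each transcript is broken into all consecutive exon triples.  A trio
defines two isoforms: the inclusion isoform (all three exons spliced) and
the skipping isoform (the two flanking exons only).  The inclusion ratio
(IR) is the inclusion isoform's expression over the summed expression of
both isoforms, with each count normalized by its isoform length so that
longer isoforms do not attract extra weight merely by catching more reads.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

from .annotation import AnnotationSet, Exon, GenomicInterval, donor_acceptor

DEFAULT_N_MIN = 4
DEFAULT_RHO = 2.0


@dataclass
class ExonTrio:
    """Three consecutive exons of one transcript and both trio isoforms."""

    trio_id: str
    transcript_ids: set[str]
    upstream: GenomicInterval
    middle: GenomicInterval
    downstream: GenomicInterval
    strand: str

    @property
    def chrom(self) -> str:
        return self.middle.chrom

    @property
    def len_skip(self) -> int:
        return len(self.upstream) + len(self.downstream)

    @property
    def len_inc(self) -> int:
        return self.len_skip + len(self.middle)

    @property
    def inclusion_coords(self) -> tuple[GenomicInterval, ...]:
        return (self.upstream, self.middle, self.downstream)

    @property
    def skipping_coords(self) -> tuple[GenomicInterval, ...]:
        return (self.upstream, self.downstream)

    @property
    def middle_key(self) -> tuple[str, str, int, int]:
        m = self.middle
        return (m.chrom, self.strand, m.start, m.end)

    def junctions(self) -> dict[str, tuple[int, int]]:
        """(donor, acceptor) of the two inclusion junctions and the skip
        junction, in genomic coordinates."""
        return {
            "up_mid": donor_acceptor(self.upstream, self.middle, self.strand),
            "mid_down": donor_acceptor(self.middle, self.downstream, self.strand),
            "skip": donor_acceptor(self.upstream, self.downstream, self.strand),
        }


@dataclass
class TrioDB:
    trios: list[ExonTrio] = field(default_factory=list)
    by_middle: dict[tuple, ExonTrio] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trios)


@dataclass
class InclusionEstimate:
    trio_id: str
    n_inc: int
    n_skip: int
    ir: float | None  # None when both counts are zero (undefined)
    se: float | None = None
    passes_cutoff: bool = True

    @property
    def defined(self) -> bool:
        return self.ir is not None


def build_txdb(ann: AnnotationSet) -> TrioDB:
    """Break every transcript into consecutive exon trios (k-2 per
    transcript); trios with identical exon intervals from different
    transcripts merge into one entry."""
    db = TrioDB()
    seen: dict[tuple, ExonTrio] = {}
    for tid in sorted(ann.transcripts):
        t = ann.transcripts[tid]
        for i in range(t.k - 2):
            u, m, d = (t.exons[i + j].interval for j in range(3))
            dedup_key = (t.strand, u.chrom, u.start, u.end, m.start, m.end, d.start, d.end)
            if dedup_key in seen:
                seen[dedup_key].transcript_ids.add(tid)
                continue
            trio = ExonTrio(
                trio_id=f"trio{len(db.trios) + 1:05d}",
                transcript_ids={tid},
                upstream=u, middle=m, downstream=d,
                strand=t.strand,
            )
            seen[dedup_key] = trio
            db.trios.append(trio)
            db.by_middle[trio.middle_key] = trio
    return db


def estimate_inclusion(
    n_inc: int, n_skip: int, len_inc: int, len_skip: int, trio_id: str = ""
) -> InclusionEstimate:
    """Length-normalized inclusion ratio.

    IR = (n_inc/len_inc) / (n_inc/len_inc + n_skip/len_skip).  A binomial
    standard error on the effective (density-weighted) counts is attached;
    zero total counts leave the IR undefined.
    """
    if n_inc < 0 or n_skip < 0:
        raise ValueError("counts must be non-negative")
    if len_inc <= 0 or len_skip <= 0:
        raise ValueError("isoform lengths must be positive")
    total = n_inc + n_skip
    if total == 0:
        return InclusionEstimate(trio_id, 0, 0, ir=None, se=None, passes_cutoff=False)
    d_inc = n_inc / len_inc
    d_skip = n_skip / len_skip
    ir = d_inc / (d_inc + d_skip)
    se = math.sqrt(ir * (1.0 - ir) / total)
    return InclusionEstimate(trio_id, n_inc, n_skip, ir=ir, se=se)


def apply_coverage_cutoff(
    est: InclusionEstimate,
    middle_exon_len: int,
    read_len: int,
    n_min: int = DEFAULT_N_MIN,
    rho: float = DEFAULT_RHO,
) -> InclusionEstimate:
    """Exon-size-dependent coverage filter.

    The trio passes iff n_inc + n_skip >= max(n_min, ceil(rho * middle_exon_len
    / read_len)): longer middle exons need proportionally more reads before
    their IR is considered reliable.  The IR itself is retained either way.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    threshold = max(n_min, math.ceil(rho * middle_exon_len / read_len))
    return replace(est, passes_cutoff=(est.n_inc + est.n_skip) >= threshold)


def classify_support(
    blocks: list[tuple[int, int]], trio: ExonTrio
) -> str | None:
    """Assign one genome-aligned read (its aligned blocks) to an isoform.

    A read supports inclusion iff it overlaps the middle exon body or spans
    either inclusion-only junction; it supports skipping iff it splices
    directly from the upstream to the downstream exon (the skip junction).
    Anything else is uninformative for this trio.
    """
    u, m, d = trio.upstream, trio.middle, trio.downstream
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if e1 == u.end and s2 == d.start or e1 == d.end and s2 == u.start:
            return "skip"
    for s, e in blocks:
        if s < m.end and m.start < e:
            return "inc"
    return None


def write_txdb_tsv(db: TrioDB, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "trio_id\tchrom\tstrand\tup_start\tup_end\tmid_start\tmid_end\t"
            "down_start\tdown_end\tlen_inc\tlen_skip\ttranscripts\n"
        )
        for t in db.trios:
            fh.write(
                f"{t.trio_id}\t{t.chrom}\t{t.strand}\t"
                f"{t.upstream.start}\t{t.upstream.end}\t"
                f"{t.middle.start}\t{t.middle.end}\t"
                f"{t.downstream.start}\t{t.downstream.end}\t"
                f"{t.len_inc}\t{t.len_skip}\t"
                f"{','.join(sorted(t.transcript_ids))}\n"
            )


def write_txdb_bed(db: TrioDB, path: str | os.PathLike) -> None:
    """Middle (cassette) exon intervals as BED6."""
    with open(path, "w") as fh:
        for t in db.trios:
            m = t.middle
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{t.trio_id}\t0\t{t.strand}\n")


def write_inclusion_tsv(estimates: list[InclusionEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("trio_id\tn_inc\tn_skip\tIR\tSE\tpasses_cutoff\n")
        for e in estimates:
            ir = f"{e.ir:.6g}" if e.ir is not None else "NA"
            se = f"{e.se:.6g}" if e.se is not None else "NA"
            fh.write(f"{e.trio_id}\t{e.n_inc}\t{e.n_skip}\t{ir}\t{se}\t{int(e.passes_cutoff)}\n")
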