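"""Junction-spanning read counting against a junction library.

Reads are aligned (externally) to the library FASTA; an alignment supports a
junction only if it crosses the record's fusion point within one gapless
aligned block, with at least ``min_anchor`` aligned bases on each side.
Record-local coordinates map back to genomic breakpoints via the flank
lengths encoded in each record.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pysam

from .errors import ConsistencyError
from .junctions import JunctionKey, JunctionLibrary, JunctionRecord

DEFAULT_MIN_ANCHOR = 8


@dataclass
class JunctionCounts:
    """Per-junction read counts plus an audit of every examined alignment."""

    sample_id: str
    counts: dict[JunctionKey, int] = field(default_factory=dict)
    total_examined: int = 0
    counted: int = 0
    unmapped: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {"non_spanning": 0, "short_anchor": 0}
    )
    multi_hit_fraction: float = 0.0

    def conservation_holds(self) -> bool:
        return (
            self.counted + sum(self.rejected.values()) + self.unmapped
            == self.total_examined
        )


def _spanning_status(
    aln: pysam.AlignedSegment, fusion: int, min_anchor: int
) -> str:
    """Classify one alignment: 'spanning', 'non_spanning' or 'short_anchor'.

    The crossing itself must lie inside a single gapless aligned block
    (an insertion/deletion at the fusion point makes the breakpoint
    ambiguous, so such reads are rejected as non-spanning).
    """
    blocks = aln.get_blocks()
    crossing = any(s <= fusion - 1 and fusion + 1 <= e for s, e in blocks)
    if not crossing:
        return "non_spanning"
    left = sum(max(0, min(e, fusion) - s) for s, e in blocks)
    right = sum(max(0, e - max(s, fusion)) for s, e in blocks)
    if left < min_anchor or right < min_anchor:
        return "short_anchor"
    return "spanning"


def count_junction_hits(
    alignments: str | os.PathLike | pysam.AlignmentFile,
    lib: JunctionLibrary,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    sample_id: str = "sample",
    unique_only: bool = False,
) -> JunctionCounts:
    """Count reads spanning each library junction.

    Secondary and supplementary alignments are ignored entirely; each read
    is counted at most once per junction.  Multi-mapped reads (one read
    spanning several records) are counted for every record unless
    ``unique_only`` is set; the multi-hit fraction is reported either way.
    """
    by_id = lib.by_id()
    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(os.fspath(alignments), check_sq=False)
        if own_handle
        else alignments
    )
    res = JunctionCounts(sample_id=sample_id)
    hits: set[tuple[str, str]] = set()  # (read, record_id) pairs that span
    try:
        for aln in af:
            if aln.is_secondary or aln.is_supplementary:
                continue
            res.total_examined += 1
            if aln.is_unmapped:
                res.unmapped += 1
                continue
            ref = aln.reference_name
            rec = by_id.get(ref)
            if rec is None:
                raise ConsistencyError(f"alignment references unknown record {ref}")
            reflen = af.get_reference_length(ref) if af.header.nreferences else None
            if reflen is not None and reflen != len(rec.sequence):
                raise ConsistencyError(
                    f"header length {reflen} for {ref} does not match library "
                    f"record length {len(rec.sequence)}"
                )
            status = _spanning_status(aln, rec.fusion_point, min_anchor)
            if status == "spanning":
                pair = (aln.query_name, ref)
                if pair in hits:
                    res.total_examined -= 1  # duplicate placement of same read
                    continue
                hits.add(pair)
                res.counted += 1
                res.counts[rec.junction.key] = res.counts.get(rec.junction.key, 0) + 1
            else:
                res.rejected[status] += 1
    finally:
        if own_handle:
            af.close()

    per_read: dict[str, int] = {}
    for read, _ref in hits:
        per_read[read] = per_read.get(read, 0) + 1
    multi_reads = {r for r, n in per_read.items() if n > 1}
    res.multi_hit_fraction = len(multi_reads) / len(per_read) if per_read else 0.0
    if unique_only and multi_reads:
        for read, ref in list(hits):
            if read in multi_reads:
                key = by_id[ref].junction.key
                res.counts[key] -= 1
                res.counted -= 1
                res.rejected.setdefault("multi_hit", 0)
                res.rejected["multi_hit"] += 1
                if res.counts[key] == 0:
                    del res.counts[key]
    return res


def junction_breakpoint(rec: JunctionRecord, local_pos: int) -> int:
    """Map a record-local position to its genomic position (strand-aware).

    Positions < up_len fall in the upstream flank (ending at the donor);
    positions >= up_len fall in the downstream flank (starting at the
    acceptor).  Truncated flanks shift the local origin, which is why the
    flank lengths travel with the record.
    """
    total = rec.up_len + rec.down_len
    if not 0 <= local_pos < total:
        raise IndexError(f"local position {local_pos} outside [0, {total})")
    j = rec.junction
    if local_pos < rec.up_len:
        offset_from_donor = rec.up_len - 1 - local_pos
        return j.donor - offset_from_donor if j.strand == "+" else j.donor + offset_from_donor
    d = local_pos - rec.up_len
    return j.acceptor + d if j.strand == "+" else j.acceptor - d


def genomic_to_local(rec: JunctionRecord, genomic_pos: int) -> int:
    """Inverse of :func:`junction_breakpoint` on the two flank intervals."""
    up, down = rec.flank_intervals()
    j = rec.junction
    if up.start <= genomic_pos < up.end:
        if j.strand == "+":
            return genomic_pos - up.start
        return up.end - 1 - genomic_pos
    if down.start <= genomic_pos < down.end:
        if j.strand == "+":
            return rec.up_len + (genomic_pos - down.start)
        return rec.up_len + (down.end - 1 - genomic_pos)
    raise IndexError(f"genomic position {genomic_pos} not in either flank")


def write_counts_tsv(res: JunctionCounts, lib: JunctionLibrary, path) -> None:
    by_key = lib.records
    with open(path, "w") as fh:
        fh.write("junction_id\tchrom\tstrand\tdonor\tacceptor\tcategory\tn_skipped\tcount\n")
        for key in sorted(by_key):
            r = by_key[key]
            j = r.junction
            fh.write(
                f"{r.record_id}\t{j.chrom}\t{j.strand}\t{j.donor}\t{j.acceptor}\t"
                f"{j.category}\t{j.n_skipped}\t{res.counts.get(key, 0)}\n"
            )


def write_bed6(res: JunctionCounts, lib: JunctionLibrary, path) -> None:
    """Genomic junction track; the BED score carries the read count."""
    with open(path, "w") as fh:
        for key in sorted(res.counts):
            r = lib.records[key]
            j = r.junction
            lo, hi = sorted((j.donor, j.acceptor))
            fh.write(
                f"{j.chrom}\t{lo}\t{hi + 1}\t{r.record_id}\t{res.counts[key]}\t{j.strand}\n"
            )
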