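"""Gene-level raw counting under the intersection_nonempty assignment rule.

For every aligned position of a read the set of genes whose exon union
covers that position is formed; the read's assignment is the intersection
of the non-empty per-position sets.  Positions touching no gene are ignored
as long as some position does — so a read hanging partially off a single
gene still counts for it, and a read fully inside gene A that brushes gene
B (where A is also present) is assigned to A.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pysam

from .annotation import AnnotationSet, GenomicInterval
from .errors import ConsistencyError

Strandedness = str  # "none" | "forward" | "reverse"


@dataclass
class GeneCounts:
    counts: dict[str, int] = field(default_factory=dict)
    no_feature: int = 0
    ambiguous: int = 0
    not_aligned: int = 0
    multi_mapped: int = 0
    total_fragments: int = 0

    def conservation_holds(self) -> bool:
        return (
            sum(self.counts.values())
            + self.no_feature
            + self.ambiguous
            + self.not_aligned
            + self.multi_mapped
            == self.total_fragments
        )


class FeatureIndex:
    """Per-gene exon-union intervals, grouped by chromosome and strand."""

    def __init__(self, ann: AnnotationSet):
        self.genes: dict[str, list[GenomicInterval]] = {
            g: ann.gene_exon_union(g) for g in ann.genes
        }
        self.by_chrom: dict[str, list[str]] = {}
        self.gene_strand: dict[str, str] = {}
        self.chroms: set[str] = set()
        for g, ivs in self.genes.items():
            self.by_chrom.setdefault(ivs[0].chrom, []).append(g)
            self.gene_strand[g] = ivs[0].strand
            self.chroms.add(ivs[0].chrom)

    def candidates(self, chrom: str, strand: str | None) -> list[str]:
        genes = self.by_chrom.get(chrom, [])
        if strand is None:
            return genes
        return [g for g in genes if self.gene_strand[g] == strand]


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect_len(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval intersection of two sorted, merged interval lists."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def assign_read(
    blocks: list[tuple[int, int]],
    features: dict[str, list[tuple[int, int]]],
) -> str | None:
    """intersection_nonempty assignment of one read's aligned blocks.

    ``features`` maps candidate gene ids to their (merged, sorted)
    exon-union intervals on the read's chromosome.  Returns the gene id,
    the string ``"ambiguous"`` or None (no feature at any position).

    Rather than walking single bases, the rule is evaluated with interval
    arithmetic: the genes overlapping every covered position are exactly
    those whose coverage of the read equals the union of all genes'
    coverage of the read.
    """
    for s, e in blocks:
        if s >= e:
            raise ValueError(f"malformed block [{s},{e})")
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if s2 < e1:
            raise ValueError("blocks must be sorted and non-overlapping")
    read_ivs = _merge_intervals(blocks)
    cover: dict[str, list[tuple[int, int]]] = {}
    for gene, ivs in features.items():
        c = _intersect_len(read_ivs, ivs)
        if c:
            cover[gene] = c
    if not cover:
        return None
    union = _merge_intervals([iv for c in cover.values() for iv in c])
    union_len = sum(e - s for s, e in union)
    full = [g for g, c in cover.items() if sum(e - s for s, e in c) == union_len]
    if len(full) == 1:
        return full[0]
    return "ambiguous"


def _fragment_strand(aln: pysam.AlignedSegment) -> str:
    """Library strand of the fragment, from read1 orientation."""
    if aln.is_paired and aln.is_read2:
        return "+" if aln.is_reverse else "-"
    return "-" if aln.is_reverse else "+"


def count_genes(
    alignments: str | os.PathLike | pysam.AlignmentFile,
    ann: AnnotationSet,
    strandedness: Strandedness = "none",
) -> GeneCounts:
    """Apply :func:`assign_read` to every primary fragment of a SAM/BAM.

    Mates of a pair are combined into one fragment (union of both mates'
    blocks) and counted once.  Secondary/supplementary alignments, and
    mapq-0 alignments declaring multiple hits (NH > 1), go to the
    multi-mapped tally and never into gene counts.
    """
    if strandedness not in ("none", "forward", "reverse"):
        raise ValueError(f"unknown strandedness {strandedness!r}")
    index = FeatureIndex(ann)
    own = not isinstance(alignments, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(os.fspath(alignments), check_sq=False)
        if own
        else alignments
    )
    res = GeneCounts()
    res.counts = {g: 0 for g in ann.genes}
    # fragments assembled per query name; mates may arrive far apart in a
    # coordinate-sorted file, so buffer the first mate until the second shows
    pending: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    pending_multi: dict[str, bool] = {}
    seen_unmapped: set[str] = set()

    def finish(chrom: str, strand: str, blocks: list, multi: bool) -> None:
        res.total_fragments += 1
        if multi:
            res.multi_mapped += 1
            return
        want: str | None = None
        if strandedness == "forward":
            want = strand
        elif strandedness == "reverse":
            want = "-" if strand == "+" else "+"
        feats = {g: [(iv.start, iv.end) for iv in index.genes[g]]
                 for g in index.candidates(chrom, want)}
        hit = assign_read(sorted(blocks), feats)
        if hit is None:
            res.no_feature += 1
        elif hit == "ambiguous":
            res.ambiguous += 1
        else:
            res.counts[hit] = res.counts.get(hit, 0) + 1

    try:
        for aln in af:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped:
                if aln.is_paired and not aln.mate_is_unmapped:
                    continue  # fragment handled via the mapped mate
                if aln.is_paired:
                    if aln.query_name in seen_unmapped:
                        seen_unmapped.discard(aln.query_name)
                        continue
                    seen_unmapped.add(aln.query_name)
                res.total_fragments += 1
                res.not_aligned += 1
                continue
            chrom = aln.reference_name
            if index.chroms and chrom not in index.chroms:
                raise ConsistencyError(
                    f"alignment chromosome {chrom} absent from annotation"
                )
            multi = aln.mapping_quality == 0 and (aln.get_tag("NH") if aln.has_tag("NH") else 1) > 1
            blocks = aln.get_blocks()
            strand = _fragment_strand(aln)
            if aln.is_paired and not aln.mate_is_unmapped:
                if aln.query_name in pending:
                    pchrom, pstrand, pblocks = pending.pop(aln.query_name)
                    pmulti = pending_multi.pop(aln.query_name)
                    finish(pchrom, pstrand, pblocks + blocks, pmulti or multi)
                else:
                    pending[aln.query_name] = (chrom, strand, blocks)
                    pending_multi[aln.query_name] = multi
            else:
                finish(chrom, strand, blocks, multi)
        for name, (chrom, strand, blocks) in pending.items():
            finish(chrom, strand, blocks, pending_multi[name])
    finally:
        if own:
            af.close()
    return res


def write_counts_tsv(res: GeneCounts, path) -> None:
    """htseq-count-compatible layout: gene rows, then the special tallies."""
    with open(path, "w") as fh:
        for gene in sorted(res.counts):
            fh.write(f"{gene}\t{res.counts[gene]}\n")
        fh.write(f"__no_feature\t{res.no_feature}\n")
        fh.write(f"__ambiguous\t{res.ambiguous}\n")
        fh.write(f"__not_aligned\t{res.not_aligned}\n")
        fh.write(f"__alignment_not_unique\t{res.multi_mapped}\n")
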