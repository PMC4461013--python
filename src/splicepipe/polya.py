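"""Poly(A) tag extraction, cleavage-site clustering and PAS annotation.

A poly(A) tag is a read ending in an untemplated adenosine run — evidence
that the fragment crossed an mRNA cleavage/polyadenylation site.  Tags are
trimmed, aligned to the genome externally, and their 3'-most aligned bases
clustered into sites.  Each site is then annotated with the polyadenylation
signal (PAS) hexamer found upstream: hexamers are searched in published
frequency order (canonical AATAAA first), so a rarer variant is reported
only when no commoner one occurs anywhere in the window.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError
from .sequences import chrom_length, fetch, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MIN_TAIL = 6
DEFAULT_MIN_TRIMMED = 15
DEFAULT_SEARCH_WINDOW = 40
DEFAULT_CLUSTER_WINDOW = 10
A_RICH_WINDOW = 10
A_RICH_THRESHOLD = 0.7


@dataclass(frozen=True)
class PolyATag:
    """A read whose terminal A-run was trimmed off."""

    read_id: str
    trimmed_seq: str
    tail_len: int

    def reconstruct(self) -> str:
        return self.trimmed_seq + "A" * self.tail_len


@dataclass(frozen=True)
class PASTable:
    """PAS hexamers ordered most-frequent first; rank 1 is the canonical signal."""

    hexamers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.hexamers)) != len(self.hexamers):
            raise ValueError("duplicate PAS hexamers")
        if any(len(h) != 6 for h in self.hexamers):
            raise ValueError("PAS entries must be hexamers")

    @property
    def canonical(self) -> str:
        return self.hexamers[0]

    @classmethod
    def default(cls) -> "PASTable":
        """Load the packaged table: canonical AATAAA plus 10 variants."""
        text = (
            resources.files("splicepipe")
            .joinpath("data/pas_hexamers.tsv")
            .read_text()
        )
        hexamers = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("hexamer"):
                continue
            hexamers.append(line.split("\t")[0].strip().upper())
        return cls(tuple(hexamers))


@dataclass
class PolyASite:
    """A clustered cleavage site with supporting-tag count and PAS annotation."""

    chrom: str
    strand: str
    cleavage_pos: int  # genomic position of the last transcribed base
    n_tags: int
    pas_hexamer: str | None = None
    pas_offset: int | None = None  # hexamer start to cleavage_pos distance
    a_rich: bool = False


# --- tag extraction ---------------------------------------------------------

@dataclass
class TagExtractionResult:
    tags: list[PolyATag]
    n_input: int = 0
    n_no_tail: int = 0
    n_short_prefix: int = 0


def extract_polya_tags(
    fastq_in: str | os.PathLike,
    fastq_out: str | os.PathLike | None = None,
    min_tail: int = DEFAULT_MIN_TAIL,
    min_trimmed: int = DEFAULT_MIN_TRIMMED,
) -> TagExtractionResult:
    """Scan a FASTQ for reads ending in an A-run and emit them trimmed.

    A read qualifies iff its maximal *uninterrupted* terminal A run has
    length >= min_tail and the remaining prefix is >= min_trimmed long.
    Qualities are truncated in lockstep with the sequence.
    """
    res = TagExtractionResult(tags=[])
    out = open(fastq_out, "w") if fastq_out is not None else None
    try:
        with open(fastq_in) as fh:
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    res.n_input += 1
                    seq_u = seq.upper()
                    tail = len(seq_u) - len(seq_u.rstrip("A"))
                    if tail < min_tail:
                        res.n_no_tail += 1
                        continue
                    trimmed = seq[: len(seq) - tail]
                    if len(trimmed) < min_trimmed:
                        res.n_short_prefix += 1
                        continue
                    read_id = title.split()[0]
                    res.tags.append(PolyATag(read_id, trimmed, tail))
                    if out is not None:
                        out.write(f"@{title}\n{trimmed}\n+\n{qual[: len(trimmed)]}\n")
            except ValueError as exc:
                raise FormatError(
                    f"malformed FASTQ near record {res.n_input + 1}: {exc}"
                ) from exc
    finally:
        if out is not None:
            out.close()
    return res


# --- site calling -----------------------------------------------------------

def _cluster_positions(
    positions: list[int], strand: str, window: int
) -> list[tuple[int, int]]:
    """Single-linkage clustering of sorted positions; returns
    (representative, n_tags) per cluster.  The representative is the modal
    position, ties broken toward the 3'-most position on the strand."""
    out = []
    positions = sorted(positions)
    cluster: list[int] = []

    def flush() -> None:
        if not cluster:
            return
        counts = Counter(cluster)
        best_n = max(counts.values())
        modal = [p for p, n in counts.items() if n == best_n]
        rep = max(modal) if strand == "+" else min(modal)
        out.append((rep, len(cluster)))

    for p in positions:
        if cluster and p - cluster[-1] > window:
            flush()
            cluster = []
        cluster.append(p)
    flush()
    return out


def call_polya_sites(
    tag_alignments: str | os.PathLike | pysam.AlignmentFile,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> list[PolyASite]:
    """Cluster aligned trimmed tags into polyadenylation sites.

    The cleavage position of one tag is its 3'-most aligned genomic base:
    reference_end-1 for forward alignments, reference_start for reverse.
    """
    own = not isinstance(tag_alignments, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(os.fspath(tag_alignments), check_sq=False)
        if own
        else tag_alignments
    )
    ends: dict[tuple[str, str], list[int]] = {}
    try:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            pos = aln.reference_start if strand == "-" else aln.reference_end - 1
            ends.setdefault((aln.reference_name, strand), []).append(pos)
    finally:
        if own:
            af.close()
    sites = []
    for (chrom, strand), positions in sorted(ends.items()):
        for rep, n in _cluster_positions(positions, strand, cluster_window):
            sites.append(PolyASite(chrom, strand, rep, n))
    return sites


# --- PAS annotation ---------------------------------------------------------

def _upstream_window(site: PolyASite, genome, window: int) -> str:
    """Transcribed-strand sequence of the `window` bases upstream of the
    cleavage position; the last base of the returned string abuts the site."""
    n = chrom_length(genome, site.chrom)
    if site.strand == "+":
        start = site.cleavage_pos - window
        if start < 0:
            logger.warning(
                "PAS window truncated at start of %s (site %d)",
                site.chrom, site.cleavage_pos,
            )
            start = 0
        return fetch(genome, site.chrom, start, site.cleavage_pos)
    end = site.cleavage_pos + 1 + window
    if end > n:
        logger.warning(
            "PAS window truncated at end of %s (site %d)", site.chrom, site.cleavage_pos
        )
        end = n
    return revcomp(fetch(genome, site.chrom, site.cleavage_pos + 1, end))


def annotate_pas(
    site: PolyASite,
    genome,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    table: PASTable | None = None,
) -> PolyASite:
    """Report the highest-ranked table hexamer found upstream of the site.

    Rank order beats proximity: a canonical signal 30 bp upstream wins over
    a variant 12 bp upstream.  Among occurrences of the winning hexamer the
    one closest to the cleavage site is reported.  The A-richness flag marks
    probable internal-priming artifacts (genomic A fraction > 0.7 in the 10
    transcribed-strand bases downstream) without filtering the site.
    """
    if table is None:
        table = PASTable.default()
    win = _upstream_window(site, genome, search_window)
    hexamer = None
    offset = None
    for h in table.hexamers:
        idx = win.rfind(h)  # closest occurrence to the cleavage site
        if idx != -1:
            hexamer = h
            offset = len(win) - idx
            break
    a_rich = _downstream_a_fraction(site, genome) > A_RICH_THRESHOLD
    return replace(site, pas_hexamer=hexamer, pas_offset=offset, a_rich=a_rich)


def _downstream_a_fraction(site: PolyASite, genome) -> float:
    n = chrom_length(genome, site.chrom)
    if site.strand == "+":
        start = site.cleavage_pos + 1
        end = min(n, start + A_RICH_WINDOW)
        seq = fetch(genome, site.chrom, start, end) if start < end else ""
    else:
        end = site.cleavage_pos
        start = max(0, end - A_RICH_WINDOW)
        seq = revcomp(fetch(genome, site.chrom, start, end)) if start < end else ""
    return seq.count("A") / len(seq) if seq else 0.0


# --- outputs ----------------------------------------------------------------

def write_sites_tsv(sites: list[PolyASite], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstrand\tcleavage_pos\tn_tags\tpas_hexamer\tpas_offset\ta_rich\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.strand}\t{s.cleavage_pos}\t{s.n_tags}\t"
                f"{s.pas_hexamer or '.'}\t"
                f"{s.pas_offset if s.pas_offset is not None else '.'}\t"
                f"{int(s.a_rich)}\n"
            )


def write_sites_bed6(sites: list[PolyASite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.cleavage_pos}\t{s.cleavage_pos + 1}\t"
                f"polyA\t{s.n_tags}\t{s.strand}\n"
            )


def write_pas_frequency_tsv(
    sites: list[PolyASite], path, table: PASTable | None = None
) -> None:
    """Frequency table of PAS hexamers over annotated sites, in rank order
    (canonical always rank 1)."""
    if table is None:
        table = PASTable.default()
    counts = Counter(s.pas_hexamer for s in sites if s.pas_hexamer)
    with open(path, "w") as fh:
        fh.write("rank\thexamer\tn_sites\n")
        for rank, h in enumerate(table.hexamers, start=1):
            fh.write(f"{rank}\t{h}\t{counts.get(h, 0)}\n")
        fh.write(f".\tnone\t{sum(1 for s in sites if not s.pas_hexamer)}\n")
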