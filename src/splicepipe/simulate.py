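"""Synthetic genomes, annotations, reads and alignments with known truth.

Every other stage is exercised against this generator: it emits a random
multi-exon annotation, spliced / unspliced / poly(A)-tailed reads, and SAM
alignments synthesized directly from the known read placements (no aligner
runs), together with a GroundTruth record of every planted quantity.  A
fixed seed makes every output byte-identical across runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .annotation import AnnotationSet, Exon, GenomicInterval, Transcript
from .errors import ConfigError
from .junctions import JunctionKey, JunctionLibrary, build_library
from .sequences import revcomp, write_fasta
from .trios import TrioDB, build_txdb

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixtures.

    Defaults describe a desk-scale experiment: half a dozen multi-exon
    genes on one small chromosome, 100 bp error-free reads, poly(A) tails
    of 8-12 A with the canonical PAS planted 15-30 bp upstream of each
    cleavage site, and 2,000 reads per interrogated exon trio.
    """

    seed: int = 0
    n_genes: int = 6
    exons_per_transcript: tuple[int, int] = (3, 6)
    exon_len_range: tuple[int, int] = (120, 300)
    intron_len_range: tuple[int, int] = (80, 400)
    intergenic_gap: int = 300
    read_len: int = 100
    n_reads: int = 1200
    frac_junction: float = 0.35
    frac_polya: float = 0.15
    boundary_length: int = 75
    min_anchor: int = 8
    tail_len_range: tuple[int, int] = (8, 12)
    pas_hexamer: str = "AATAAA"
    pas_offset_range: tuple[int, int] = (15, 30)
    trio_psi: tuple[float, ...] = (0.1, 0.5, 0.9)
    reads_per_trio: int = 2000
    error_rate: float = 0.0

    def validate(self) -> None:
        for f in (self.frac_junction, self.frac_polya, self.error_rate):
            if not 0.0 <= f <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.frac_junction + self.frac_polya > 1.0:
            raise ConfigError("read fractions exceed 1")
        if self.read_len > self.exon_len_range[0]:
            raise ConfigError(
                "read_len exceeds the shortest exon; unspliced reads "
                "could not be placed inside one exon"
            )
        if self.pas_offset_range[0] < 6:
            raise ConfigError("PAS offset must leave room for the hexamer")
        if len(self.pas_hexamer) != 6:
            raise ConfigError("planted PAS must be a hexamer")


@dataclass
class GroundTruth:
    """Every planted quantity, keyed the way the recovering module keys it."""

    junction_counts: dict[JunctionKey, int] = field(default_factory=dict)
    polya_sites: list[dict] = field(default_factory=list)
    trio_truth: list[dict] = field(default_factory=list)
    gene_counts: dict[str, int] = field(default_factory=dict)

    def write_tsv_bundle(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "truth_junctions.tsv"), "w") as fh:
            fh.write("chrom\tstrand\tdonor\tacceptor\tcount\n")
            for (c, s, d, a), n in sorted(self.junction_counts.items()):
                fh.write(f"{c}\t{s}\t{d}\t{a}\t{n}\n")
        with open(os.path.join(outdir, "truth_polya.tsv"), "w") as fh:
            fh.write("chrom\tstrand\tcleavage_pos\tpas_hexamer\tpas_offset\tn_tags\n")
            for s in self.polya_sites:
                fh.write(
                    f"{s['chrom']}\t{s['strand']}\t{s['cleavage_pos']}\t"
                    f"{s['pas_hexamer']}\t{s['pas_offset']}\t{s['n_tags']}\n"
                )
        with open(os.path.join(outdir, "truth_trios.tsv"), "w") as fh:
            fh.write("trio_id\tpsi\tn_inc\tn_skip\tlen_inc\tlen_skip\n")
            for t in self.trio_truth:
                fh.write(
                    f"{t['trio_id']}\t{t['psi']}\t{t['n_inc']}\t{t['n_skip']}\t"
                    f"{t['len_inc']}\t{t['len_skip']}\n"
                )
        with open(os.path.join(outdir, "truth_genes.tsv"), "w") as fh:
            fh.write("gene_id\tcount\n")
            for g, n in sorted(self.gene_counts.items()):
                fh.write(f"{g}\t{n}\n")


def make_toy_genome_annotation(
    cfg: SimConfig,
) -> tuple[dict[str, str], AnnotationSet]:
    """Random chromosome with multi-exon genes on both strands.

    A PAS hexamer is planted 15-30 bp (configurable) upstream of every
    transcript's cleavage site on the transcribed strand, so the poly(A)
    stage has a recoverable signal.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    seq: list[str] = []
    cursor = cfg.intergenic_gap
    ann = AnnotationSet()
    pas_truth: dict[str, tuple[int, int]] = {}  # tid -> (cleavage_pos, offset)
    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        k = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
        ivs = []
        pos = cursor
        for e in range(k):
            elen = int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
            ivs.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen
            if e < k - 1:
                pos += int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
        cursor = pos + cfg.intergenic_gap
        ordered = ivs if strand == "+" else ivs[::-1]
        exons = [Exon(iv, r) for r, iv in enumerate(ordered, start=1)]
        tid = f"T{g + 1}"
        ann.add(Transcript(tid, f"G{g + 1}", chrom, strand, exons))
    length = cursor + cfg.intergenic_gap
    genome_arr = rng.choice(BASES, size=length)
    # plant PAS upstream of each cleavage site, on the transcribed strand
    for tid, t in ann.transcripts.items():
        off = int(rng.integers(cfg.pas_offset_range[0], cfg.pas_offset_range[1] + 1))
        last = t.exons[-1].interval
        if t.strand == "+":
            cleav = last.end - 1
            genome_arr[cleav - off : cleav - off + 6] = list(cfg.pas_hexamer)
        else:
            cleav = last.start
            genome_arr[cleav + off - 5 : cleav + off + 1] = list(revcomp(cfg.pas_hexamer))
        pas_truth[tid] = (cleav, off)
    genome = {chrom: "".join(genome_arr)}
    ann.pas_truth = pas_truth  # carried to simulate_reads
    return genome, ann


@dataclass
class SimulatedData:
    fastq: str
    genome_sam: str
    library_sam: str
    tags_sam: str
    genome_fasta: str
    gtf: str
    library: JunctionLibrary
    txdb: TrioDB
    truth: GroundTruth


def _sam_header(genome: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
        }
    )


def _lib_header(lib: JunctionLibrary) -> pysam.AlignmentHeader:
    ids = sorted(lib.by_id())
    lens = {rid: len(rec.sequence) for rid, rec in lib.by_id().items()}
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": rid, "LN": lens[rid]} for rid in ids],
        }
    )


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = str(rng.choice(BASES[BASES != out[i]]))
    return "".join(out)


def _aln(header, name, ref, pos, seq, reverse=False, cigar=None):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_name = ref
    a.reference_start = pos
    a.query_sequence = seq
    a.cigarstring = cigar or f"{len(seq)}M"
    a.mapping_quality = 60
    a.flag = 16 if reverse else 0
    return a


def simulate_reads(
    genome: dict[str, str],
    ann: AnnotationSet,
    cfg: SimConfig,
    outdir: str | os.PathLike,
) -> SimulatedData:
    """Emit FASTQ reads plus SAM alignments synthesized from known placements.

    Three read classes: unspliced exonic reads (aligned to the genome, the
    input of gene counting), junction-spanning reads (aligned to the
    junction library with anchors >= cfg.min_anchor), and poly(A) reads
    (transcript 3' end plus an untemplated A-tail; the trimmed tag's genome
    alignment is emitted separately).  Trio inclusion/skipping support is
    simulated at count level with length-proportional sampling around the
    true inclusion fraction psi.
    """
    cfg.validate()
    if not hasattr(ann, "pas_truth"):
        raise ConfigError(
            "annotation must come from make_toy_genome_annotation (it carries "
            "the planted PAS positions the poly(A) reads are built from)"
        )
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    truth = GroundTruth()
    lib = build_library(ann, genome, cfg.boundary_length)
    txdb = build_txdb(ann)
    paths = {
        "fastq": os.path.join(outdir, "reads.fastq"),
        "genome_sam": os.path.join(outdir, "genome.sam"),
        "library_sam": os.path.join(outdir, "library.sam"),
        "tags_sam": os.path.join(outdir, "tags.sam"),
        "genome_fasta": os.path.join(outdir, "genome.fa"),
        "gtf": os.path.join(outdir, "annotation.gtf"),
    }
    write_fasta(genome, paths["genome_fasta"])
    from .annotation import write_gtf

    write_gtf(ann, paths["gtf"])

    n_junc = int(round(cfg.n_reads * cfg.frac_junction))
    n_polya = int(round(cfg.n_reads * cfg.frac_polya))
    n_exonic = cfg.n_reads - n_junc - n_polya
    tids = sorted(ann.transcripts)
    ghead = _sam_header(genome)
    lhead = _lib_header(lib)

    fastq = open(paths["fastq"], "w")
    gsam = pysam.AlignmentFile(paths["genome_sam"], "w", header=ghead)
    lsam = pysam.AlignmentFile(paths["library_sam"], "w", header=lhead)
    tsam = pysam.AlignmentFile(paths["tags_sam"], "w", header=ghead)
    read_no = 0

    def emit_fastq(name: str, seq: str) -> None:
        fastq.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")

    try:
        # --- unspliced exonic reads -> genome SAM (gene counting input)
        for _ in range(n_exonic):
            tid = tids[int(rng.integers(len(tids)))]
            t = ann.transcripts[tid]
            fitting = [e for e in t.exons if len(e) >= cfg.read_len]
            ex = fitting[int(rng.integers(len(fitting)))]
            start = int(rng.integers(ex.interval.start, ex.interval.end - cfg.read_len + 1))
            plus_seq = genome[t.chrom][start : start + cfg.read_len]
            read_no += 1
            name = f"exonic{read_no}"
            reverse = t.strand == "-"
            read_seq = _mutate(revcomp(plus_seq) if reverse else plus_seq, rng, cfg.error_rate)
            emit_fastq(name, read_seq)
            sam_seq = revcomp(read_seq) if reverse else read_seq
            gsam.write(_aln(ghead, name, t.chrom, start, sam_seq, reverse=reverse))
            truth.gene_counts[t.gene_id] = truth.gene_counts.get(t.gene_id, 0) + 1

        # --- junction-spanning reads -> library SAM
        rec_ids = sorted(lib.by_id())
        by_id = lib.by_id()
        for _ in range(n_junc):
            rid = rec_ids[int(rng.integers(len(rec_ids)))]
            rec = by_id[rid]
            lo = max(0, rec.up_len - (cfg.read_len - cfg.min_anchor))
            hi = rec.up_len - cfg.min_anchor
            hi = min(hi, rec.up_len + rec.down_len - cfg.read_len)
            if hi < lo:
                continue  # record too short for this read length
            start = int(rng.integers(lo, hi + 1))
            seq = rec.sequence[start : start + cfg.read_len]
            read_no += 1
            name = f"junc{read_no}"
            read_seq = _mutate(seq, rng, cfg.error_rate)
            emit_fastq(name, read_seq)
            lsam.write(_aln(lhead, name, rid, start, read_seq))
            key = rec.junction.key
            truth.junction_counts[key] = truth.junction_counts.get(key, 0) + 1

        # --- poly(A) reads: transcript 3' end + untemplated A tail
        site_tags: dict[str, int] = {}
        for i in range(n_polya):
            tid = tids[i % len(tids)]
            t = ann.transcripts[tid]
            cleav, off = ann.pas_truth[tid]
            tail = int(rng.integers(cfg.tail_len_range[0], cfg.tail_len_range[1] + 1))
            trim_len = cfg.read_len - tail
            last = t.exons[-1].interval
            trim_len = min(trim_len, len(last))
            if t.strand == "+":
                tag_plus = genome[t.chrom][cleav + 1 - trim_len : cleav + 1]
                tag_seq = tag_plus
                tag_pos, tag_rev = cleav + 1 - trim_len, False
            else:
                tag_plus = genome[t.chrom][cleav : cleav + trim_len]
                tag_seq = revcomp(tag_plus)
                tag_pos, tag_rev = cleav, True
            read_no += 1
            name = f"polya{read_no}"
            read_seq = _mutate(tag_seq + "A" * tail, rng, cfg.error_rate)
            emit_fastq(name, read_seq)
            trimmed = read_seq[:trim_len]
            sam_seq = revcomp(trimmed) if tag_rev else trimmed
            tsam.write(_aln(ghead, name, t.chrom, tag_pos, sam_seq, reverse=tag_rev))
            site_tags[tid] = site_tags.get(tid, 0) + 1
        for tid, n in sorted(site_tags.items()):
            t = ann.transcripts[tid]
            cleav, off = ann.pas_truth[tid]
            truth.polya_sites.append(
                {
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "cleavage_pos": cleav,
                    "pas_hexamer": cfg.pas_hexamer,
                    "pas_offset": off,
                    "n_tags": n,
                }
            )

        # --- trio support counts (length-proportional sampling around psi)
        usable = txdb.trios
        for i, psi in enumerate(cfg.trio_psi):
            if i >= len(usable):
                break
            trio = usable[i]
            p_inc = psi * trio.len_inc / (psi * trio.len_inc + (1 - psi) * trio.len_skip)
            n_inc = int(rng.binomial(cfg.reads_per_trio, p_inc))
            truth.trio_truth.append(
                {
                    "trio_id": trio.trio_id,
                    "psi": psi,
                    "n_inc": n_inc,
                    "n_skip": cfg.reads_per_trio - n_inc,
                    "len_inc": trio.len_inc,
                    "len_skip": trio.len_skip,
                }
            )
    finally:
        fastq.close()
        gsam.close()
        lsam.close()
        tsam.close()

    truth.write_tsv_bundle(os.path.join(outdir, "truth"))
    return SimulatedData(
        fastq=paths["fastq"],
        genome_sam=paths["genome_sam"],
        library_sam=paths["library_sam"],
        tags_sam=paths["tags_sam"],
        genome_fasta=paths["genome_fasta"],
        gtf=paths["gtf"],
        library=lib,
        txdb=txdb,
        truth=truth,
    )


def simulate_count_matrix(
    seed: int,
    n_features: int = 1000,
    n_per_condition: int = 3,
    base_mean: float = 100.0,
    alpha: float = 0.1,
    n_diff: int = 0,
    fold_change: float = 4.0,
):
    """NB count matrix for two conditions with a designated changed subset.

    The first ``n_diff`` features carry ``fold_change`` in condition B;
    the rest are null.  alpha=0 draws Poisson counts.  Returns
    (DataFrame features x samples, condition map, boolean truth vector).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    samples = [f"A{i + 1}" for i in range(n_per_condition)] + [
        f"B{i + 1}" for i in range(n_per_condition)
    ]
    cond = {s: s[0] for s in samples}
    means_a = np.full(n_features, base_mean)
    means_b = means_a.copy()
    means_b[:n_diff] *= fold_change
    cols = {}
    for s in samples:
        mu = means_b if s.startswith("B") else means_a
        if alpha <= 0:
            cols[s] = rng.poisson(mu)
        else:
            size = 1.0 / alpha
            p = size / (size + mu)
            cols[s] = rng.negative_binomial(size, p)
    counts = pd.DataFrame(cols, index=[f"f{i + 1}" for i in range(n_features)])
    is_diff = np.zeros(n_features, dtype=bool)
    is_diff[:n_diff] = True
    return counts, cond, is_diff
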