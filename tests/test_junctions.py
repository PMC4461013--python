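import itertools

import numpy as np
import pytest

from splicepipe.annotation import AnnotationSet
from splicepipe.junctions import (
    KNOWN,
    NOVEL,
    build_library,
    enumerate_known_junctions,
    enumerate_novel_junctions,
    read_library_fasta,
    write_library_fasta,
    write_manifest_tsv,
)
from splicepipe.sequences import revcomp

from .conftest import make_transcript


def brute_force_pairs(k):
    """Oracle: all ordered exon pairs; adjacent = known, gap >= 1 = novel."""
    known = [(i, i + 1) for i in range(k - 1)]
    novel = [(i, j) for i, j in itertools.combinations(range(k), 2) if j > i + 1]
    return known, novel


def spaced_transcript(k, strand="+", start=0, exon_len=100, intron_len=150):
    ivs, pos = [], start
    for _ in range(k):
        ivs.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    return make_transcript(f"T{k}{strand}", "G", "chr1", strand, ivs)


@pytest.mark.parametrize("k,expected", [(2, 0), (3, 1), (5, 6)])
def test_novel_junction_totals(k, expected):
    t = spaced_transcript(k)
    novel = enumerate_novel_junctions(t)
    assert len(novel) == expected == (k - 1) * (k - 2) // 2


@pytest.mark.parametrize("k", range(1, 13))
@pytest.mark.parametrize("strand", ["+", "-"])
def test_combinatorics_match_brute_force_oracle(k, strand):
    t = spaced_transcript(k, strand)
    known_oracle, novel_oracle = brute_force_pairs(k)
    known = enumerate_known_junctions(t)
    novel = enumerate_novel_junctions(t)
    assert len(known) == len(known_oracle) == k - 1
    assert len(novel) == len(novel_oracle) == (k - 1) * (k - 2) // 2
    # every oracle pair appears with the right skip count
    got = {(j.donor, j.acceptor): j.n_skipped for j in novel}
    for i, j in novel_oracle:
        d, a = (
            (t.exons[i].interval.end - 1, t.exons[j].interval.start)
            if strand == "+"
            else (t.exons[i].interval.start, t.exons[j].interval.end - 1)
        )
        assert got[(d, a)] == j - i - 1
    single_skip = [j for j in novel if j.n_skipped == 1]
    assert len(single_skip) == max(0, k - 2)


def test_randomized_exon_lengths_keep_counts(toy_genome):
    rng = np.random.default_rng(17)
    for _ in range(10):
        k = int(rng.integers(1, 13))
        lens = rng.integers(30, 200, size=k)
        ivs, pos = [], 0
        for n in lens:
            ivs.append((pos, pos + int(n)))
            pos += int(n) + int(rng.integers(60, 200))
        t = make_transcript("T", "G", "chr1", rng.choice(["+", "-"]), ivs)
        assert len(enumerate_known_junctions(t)) == k - 1
        assert len(enumerate_novel_junctions(t)) == (k - 1) * (k - 2) // 2


def test_truncated_flank_from_short_exon(toy_genome):
    # exon lengths (100, 80, 30) at L=50: exon2->exon3 has up 50, down 30
    t = make_transcript(
        "T1", "G1", "chr1", "+", [(0, 100), (200, 280), (400, 430)]
    )
    ann = AnnotationSet()
    ann.add(t)
    lib = build_library(ann, toy_genome, L=50)
    key = ("chr1", "+", 279, 400)
    rec = lib.records[key]
    assert (rec.up_len, rec.down_len) == (50, 30)
    assert len(rec.sequence) == rec.up_len + rec.down_len == 80


def test_sequences_match_genome_base_by_base(toy_genome, toy_annotation):
    lib = build_library(toy_annotation, toy_genome, L=60)
    chrom = toy_genome["chr1"]
    for rec in lib.records.values():
        up, down = rec.flank_intervals()
        if rec.junction.strand == "+":
            expected = chrom[up.start : up.end] + chrom[down.start : down.end]
        else:
            expected = revcomp(chrom[up.start : up.end]) + revcomp(
                chrom[down.start : down.end]
            )
        assert rec.sequence == expected


def test_shared_intron_dedupes_across_transcripts(toy_genome):
    ann = AnnotationSet()
    ann.add(make_transcript("Ta", "G", "chr1", "+", [(0, 100), (300, 400)]))
    ann.add(make_transcript("Tb", "G", "chr1", "+", [(0, 100), (300, 400), (600, 700)]))
    lib = build_library(ann, toy_genome, L=50)
    rec = lib.records[("chr1", "+", 99, 300)]
    assert rec.source_transcripts == {"Ta", "Tb"}


def test_known_in_any_transcript_beats_novel(toy_genome):
    ann = AnnotationSet()
    # in Ta exon1->exon3 junction skips exon2; Tb has those exons adjacent
    ann.add(make_transcript("Ta", "G", "chr1", "+", [(0, 100), (300, 400), (600, 700)]))
    ann.add(make_transcript("Tb", "G", "chr1", "+", [(0, 100), (600, 700)]))
    lib = build_library(ann, toy_genome, L=50)
    rec = lib.records[("chr1", "+", 99, 600)]
    assert rec.junction.category == KNOWN
    known_keys = {k for k, r in lib.records.items() if r.junction.category == KNOWN}
    novel_keys = {k for k, r in lib.records.items() if r.junction.category == NOVEL}
    assert known_keys.isdisjoint(novel_keys)


def test_per_transcript_totals_in_library(toy_genome):
    t = spaced_transcript(7)
    ann = AnnotationSet()
    ann.add(t)
    lib = build_library(ann, toy_genome, L=50)
    k = t.k
    assert len(lib) == k * (k - 1) // 2  # known + novel, no duplicates


def test_flank_truncation_commutes_with_boundary(toy_genome, toy_annotation):
    """A library built at L=150 then restricted to 50 bp flanks equals the
    library built directly at L=50."""
    lib150 = build_library(toy_annotation, toy_genome, L=150)
    lib50 = build_library(toy_annotation, toy_genome, L=50)
    assert set(lib150.records) == set(lib50.records)
    for key, r50 in lib50.records.items():
        r150 = lib150.records[key]
        up = min(50, r150.up_len)
        down = min(50, r150.down_len)
        restricted = (
            r150.sequence[r150.up_len - up : r150.up_len + down]
        )
        assert (up, down) == (r50.up_len, r50.down_len)
        assert restricted == r50.sequence


def test_fasta_round_trip(tmp_path, toy_genome, toy_annotation):
    lib = build_library(toy_annotation, toy_genome, L=50)
    path = tmp_path / "lib.fa"
    write_library_fasta(lib, path)
    back = read_library_fasta(path)
    assert set(back.records) == set(lib.records)
    for key, rec in lib.records.items():
        b = back.records[key]
        assert b.junction == rec.junction
        assert (b.up_len, b.down_len, b.sequence) == (
            rec.up_len, rec.down_len, rec.sequence,
        )


def test_fasta_header_encodes_flank_lengths(tmp_path, toy_genome):
    t = make_transcript("T1", "G1", "chr1", "+", [(0, 100), (200, 280), (400, 430)])
    ann = AnnotationSet()
    ann.add(t)
    lib = build_library(ann, toy_genome, L=50)
    path = tmp_path / "lib.fa"
    write_library_fasta(lib, path)
    headers = [l[1:].strip() for l in path.read_text().splitlines() if l.startswith(">")]
    target = [h for h in headers if h.split("|")[3] == "279"][0]
    fields = target.split("|")
    assert fields[5] == "50" and fields[6] == "30"


def test_manifest_lists_every_record(tmp_path, toy_genome, toy_annotation):
    lib = build_library(toy_annotation, toy_genome, L=50)
    p = tmp_path / "manifest.tsv"
    write_manifest_tsv(lib, p)
    lines = p.read_text().strip().splitlines()
    assert len(lines) == len(lib) + 1
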