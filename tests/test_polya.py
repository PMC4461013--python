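import pysam
import pytest

from splicepipe.errors import FormatError
from splicepipe.polya import (
    PASTable,
    PolyASite,
    annotate_pas,
    call_polya_sites,
    extract_polya_tags,
    write_pas_frequency_tsv,
)


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def write_tag_sam(path, placements, chrom_len=10000):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": chrom_len}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, pos, length, reverse in placements:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.reference_name = "chr1"
            a.reference_start = pos
            a.cigarstring = f"{length}M"
            a.query_sequence = "C" * length
            a.mapping_quality = 60
            a.flag = 16 if reverse else 0
            out.write(a)
    return path


class TestTagExtraction:
    def test_qualifying_read_is_trimmed(self, tmp_path):
        fq = write_fastq(tmp_path / "r.fq", [("r1", "ACGTACGTAC" + "A" * 8)])
        res = extract_polya_tags(fq, min_tail=6, min_trimmed=10)
        (tag,) = res.tags
        assert tag.tail_len == 8 and tag.trimmed_seq == "ACGTACGTAC"

    def test_no_terminal_run_is_not_a_tag(self, tmp_path):
        fq = write_fastq(tmp_path / "r.fq", [("r1", "ACGTACGTACGT")])
        res = extract_polya_tags(fq, min_tail=6, min_trimmed=10)
        assert res.tags == [] and res.n_no_tail == 1

    def test_all_a_read_rejected_short_prefix(self, tmp_path):
        fq = write_fastq(tmp_path / "r.fq", [("r1", "A" * 12)])
        res = extract_polya_tags(fq, min_tail=6, min_trimmed=10)
        assert res.tags == [] and res.n_short_prefix == 1

    def test_reconstruction_and_conservation(self, tmp_path):
        reads = [
            ("a", "ACGTACGTACGTACGTAC" + "A" * 7),
            ("b", "CGCGCGCGCGCGCGCG"),
            ("c", "AAAA" + "A" * 8),
            ("d", "TTTTTTTTTTTTTTTTTTTT" + "A" * 6),
        ]
        fq = write_fastq(tmp_path / "r.fq", reads)
        res = extract_polya_tags(fq, min_tail=6, min_trimmed=15)
        originals = dict(reads)
        for tag in res.tags:
            assert tag.reconstruct() == originals[tag.read_id]
        assert len(res.tags) + res.n_no_tail + res.n_short_prefix == res.n_input

    def test_trimmed_fastq_qualities_in_lockstep(self, tmp_path):
        fq = write_fastq(tmp_path / "r.fq", [("r1", "ACGTACGTACGTACGT" + "A" * 6)])
        out = tmp_path / "t.fq"
        extract_polya_tags(fq, out, min_tail=6, min_trimmed=10)
        lines = out.read_text().splitlines()
        assert len(lines[1]) == len(lines[3]) == 16

    def test_malformed_fastq_names_record(self, tmp_path):
        p = tmp_path / "bad.fq"
        p.write_text("@r1\nACGT\nplus-line-wrong\nIIII\n")
        with pytest.raises(FormatError):
            extract_polya_tags(p)


class TestSiteCalling:
    def test_mode_position_wins(self, tmp_path):
        sam = write_tag_sam(
            tmp_path / "t.sam",
            [("a", 971, 30, False), ("b", 972, 30, False), ("c", 971, 30, False)],
        )
        # 3' ends: 1000, 1001, 1000 -> one site at the mode 1000, n_tags 3
        (site,) = call_polya_sites(sam, cluster_window=5)
        assert (site.cleavage_pos, site.n_tags, site.strand) == (1000, 3, "+")

    def test_positions_beyond_window_stay_separate(self, tmp_path):
        sam = write_tag_sam(
            tmp_path / "t.sam", [("a", 971, 30, False), ("b", 1021, 30, False)]
        )
        sites = call_polya_sites(sam, cluster_window=5)
        assert [s.cleavage_pos for s in sites] == [1000, 1050]

    def test_minus_strand_cleavage_is_leftmost_base(self, tmp_path):
        sam = write_tag_sam(tmp_path / "t.sam", [("a", 200, 50, True)])
        (site,) = call_polya_sites(sam)
        assert (site.cleavage_pos, site.strand) == (200, "-")

    def test_tie_breaks_to_most_three_prime(self, tmp_path):
        sam = write_tag_sam(
            tmp_path / "t.sam",
            [("a", 971, 30, False), ("b", 973, 30, False)],
        )
        (site,) = call_polya_sites(sam, cluster_window=5)
        assert site.cleavage_pos == 1002  # + strand: larger position is 3'

    def test_tag_conservation(self, tmp_path):
        placements = [(f"r{i}", 100 * i, 30, i % 2 == 0) for i in range(1, 8)]
        sam = write_tag_sam(tmp_path / "t.sam", placements)
        sites = call_polya_sites(sam, cluster_window=10)
        assert sum(s.n_tags for s in sites) == len(placements)


class TestPASAnnotation:
    def make_genome(self, window):
        # cleavage at position 500 on +; bases [460,500) form the window
        seq = ["C"] * 1000
        for i, b in enumerate(window):
            seq[460 + i] = b
        return {"chr1": "".join(seq)}

    def test_single_canonical_hit(self):
        w = ["C"] * 40
        w[40 - 16 : 40 - 10] = list("AATAAA")  # starts 16 bases upstream
        genome = self.make_genome(w)
        site = annotate_pas(PolyASite("chr1", "+", 500, 1), genome, 40)
        assert (site.pas_hexamer, site.pas_offset) == ("AATAAA", 16)

    def test_rank_beats_proximity(self):
        w = ["C"] * 40
        w[40 - 12 : 40 - 6] = list("ATTAAA")
        w[40 - 30 : 40 - 24] = list("AATAAA")
        site = annotate_pas(PolyASite("chr1", "+", 500, 1), self.make_genome(w), 40)
        assert site.pas_hexamer == "AATAAA"

    def test_closest_occurrence_of_winning_hexamer(self):
        w = ["C"] * 40
        w[40 - 30 : 40 - 24] = list("AATAAA")
        w[40 - 14 : 40 - 8] = list("AATAAA")
        site = annotate_pas(PolyASite("chr1", "+", 500, 1), self.make_genome(w), 40)
        assert site.pas_offset == 14

    def test_no_hit_reports_none(self):
        site = annotate_pas(
            PolyASite("chr1", "+", 500, 1), self.make_genome(["C"] * 40), 40
        )
        assert site.pas_hexamer is None and site.pas_offset is None

    def test_minus_strand_window_is_reverse_complemented(self):
        # minus-strand cleavage at 500; upstream = higher coordinates
        seq = ["C"] * 1000
        # plant revcomp(AATAAA) = TTTATT so the hexamer starts 20 nt upstream
        # in transcript coordinates
        seq[515:521] = list("TTTATT")
        genome = {"chr1": "".join(seq)}
        site = annotate_pas(PolyASite("chr1", "-", 500, 1), genome, 40)
        assert (site.pas_hexamer, site.pas_offset) == ("AATAAA", 20)

    def test_window_truncated_at_chrom_start(self):
        genome = {"chr1": "C" * 50}
        site = annotate_pas(PolyASite("chr1", "+", 10, 1), genome, 40)
        assert site.pas_hexamer is None

    def test_a_rich_flag(self):
        seq = ["C"] * 1000
        seq[501:511] = list("AAAAAAAAAA")
        site = annotate_pas(PolyASite("chr1", "+", 500, 1), {"chr1": "".join(seq)}, 40)
        assert site.a_rich


def test_default_pas_table_is_canonical_plus_ten_variants():
    table = PASTable.default()
    assert len(table.hexamers) == 11
    assert table.canonical == "AATAAA"
    assert len(set(table.hexamers)) == 11
    assert all(len(h) == 6 for h in table.hexamers)


def test_pas_frequency_tsv_ranks_stable(tmp_path):
    sites = [
        PolyASite("chr1", "+", 100, 2, pas_hexamer="ATTAAA"),
        PolyASite("chr1", "+", 300, 1, pas_hexamer="AATAAA"),
        PolyASite("chr1", "+", 500, 1, pas_hexamer=None),
    ]
    p = tmp_path / "pas.tsv"
    write_pas_frequency_tsv(sites, p)
    lines = [l.split("\t") for l in p.read_text().strip().splitlines()[1:]]
    assert lines[0][1] == "AATAAA" and lines[0][0] == "1"
    counts = {l[1]: int(l[2]) for l in lines}  # sites per hexamer
    assert counts["AATAAA"] == 1 and counts["ATTAAA"] == 1 and counts["none"] == 1


def test_planted_sites_recovered_exactly(sim_bundle):
    """Error-free simulation: every planted cleavage position is called at
    the exact position with the planted hexamer annotated."""
    cfg, genome, _ann, sim = sim_bundle
    res = extract_polya_tags(sim.fastq, min_tail=6, min_trimmed=15)
    assert len(res.tags) == sum(s["n_tags"] for s in sim.truth.polya_sites)
    sites = call_polya_sites(sim.tags_sam)
    sites = [annotate_pas(s, genome) for s in sites]
    got = {(s.chrom, s.strand, s.cleavage_pos): s for s in sites}
    for planted in sim.truth.polya_sites:
        key = (planted["chrom"], planted["strand"], planted["cleavage_pos"])
        assert key in got
        s = got[key]
        assert s.n_tags == planted["n_tags"]
        assert s.pas_hexamer == planted["pas_hexamer"]
    assert len(got) == len(sim.truth.polya_sites)
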