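# splicepipe

Tools for the bespoke computational stages of a short-read RNA-seq
analysis: combinatorial splice-junction library construction,
junction-spanning read counting, poly(A)/polyadenylation-signal (PAS) site
detection, cassette-exon (exon-trio) inclusion ratios, gene-level raw
counting under the `intersection_nonempty` rule, and two-condition
differential tests (chi-square on inclusion counts; a simplified
negative-binomial exact test on raw counts; Benjamini-Hochberg FDR).

It is aimed at people building or dissecting RNA-seq pipelines who want
the non-aligner stages as a tested, scriptable library: alignment itself
(TopHat/Bowtie-class tools), transcript assembly and fusion detection are
deliberately out of scope — the package consumes SAM/BAM produced
elsewhere (or by its bundled simulator) and produces plain TSV/BED/FASTA.

## The core models

**Junction combinatorics.** A transcript with *k* exons exposes *k−1*
known splice junctions (adjacent exon pairs). Exhaustively skipping every
run of consecutive inner exons joins exon *i* to exon *j* for all
*j ≥ i+2*, adding C(k−1, 2) = (k−1)(k−2)/2 novel junctions, of which the
single-skip subset has size *k−2*. Each junction record carries up to *L*
bases of flanking exon on each side (L ∈ {50, 75, 100, 150} by default);
a flanking exon shorter than *L* contributes a truncated flank, and the
flank lengths are encoded in the FASTA header so the fusion point stays
recoverable. A read supports a junction iff its alignment crosses the
fusion point in one gapless block with ≥ `min_anchor` (default 8) aligned
bases on each side.

**Poly(A) sites.** Reads ending in an untemplated A-run (≥ 6 by default)
are trimmed and their aligned 3′ ends clustered (10 bp window, modal
position) into cleavage sites. Each site is annotated with the PAS
hexamer found in the 40 bp upstream on the transcribed strand; the table
(canonical AAUAAA, written AATAAA in DNA, plus 10 variants) is searched
in frequency order, so rank beats proximity.

**Cassette exons.** Every consecutive exon triple of every transcript
forms a trio with an inclusion isoform (all three exons, length
`len_inc`) and a skipping isoform (flanks only, `len_skip`). The
inclusion ratio is length-normalized:

    IR = (n_inc / len_inc) / (n_inc / len_inc + n_skip / len_skip)

with an exon-size-dependent coverage cutoff
`n_inc + n_skip ≥ max(n_min, ⌈ρ·middle_len/read_len⌉)`.

**Differential tests.** Inclusion counts are compared with a Pearson
chi-square on the 2×2 table (statistic N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
1 df). Raw counts (genes, junctions, poly(A) sites) use median-of-ratios
size factors and a conditional NB exact test whose variance is shot noise
plus overdispersion, var = μ + αμ², with α estimated from replicates and
pooled across features of similar expression. Each family of p-values is
BH-adjusted separately.

## Worked example

Simulate a toy experiment and run the pipeline on it:

```
splicepipe simulate --seed 8 --outdir sim
splicepipe run --gtf sim/annotation.gtf --genome sim/genome.fa \
    --reads sim/reads.fastq --library-alignments sim/library.sam \
    --genome-alignments sim/genome.sam --tag-alignments sim/tags.sam \
    --outdir out
```

which prints, for this seed:

```
junctions: completed 47 junctions, 420 spanning reads
polya: completed 180 tags, 6 sites
trios: completed 14 trios
counts: completed 600 assigned
```

`47 junctions` is the full library (known + combinatorial skips) of the
6 simulated genes; every one of the 420 junction reads crossed a fusion
point with sufficient anchors; the 180 poly(A) tags cluster into exactly
one cleavage site per gene (6), each annotated with the planted AATAAA;
and all 600 unspliced reads were assigned to their source gene. Per-stage
tables land in `out/` (`junction_counts.tsv`, `polya_sites.tsv`,
`txdb.tsv`, `gene_counts.tsv`) plus a `manifest.jsonl` with one
status line per stage.

The same stages are available as a library:

```python
from splicepipe import read_gtf, build_library, count_junction_hits
ann = read_gtf("sim/annotation.gtf")
lib = build_library(ann, genome, L=75)      # genome: dict or pyfaidx.Fasta
res = count_junction_hits("sim/library.sam", lib)
```

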