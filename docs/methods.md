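# Methods

This note records the models splicepipe implements, the parameters that
matter, the numerical choices made where the design was open, and what the
synthetic fixtures do and do not demonstrate.

## Coordinates and gene models

All internal coordinates are 0-based half-open; GTF I/O converts from the
1-based inclusive file convention at the boundary. Exon ranks are 1-based
in transcript (5′→3′) order, which is ascending genomic order on the +
strand and descending on −. A junction's *donor* is the genomic position
of the exonic base 3′-adjacent to the intron and its *acceptor* the first
exonic base after it, both strand-aware; junction identity is the tuple
(chrom, strand, donor, acceptor). Transcripts with overlapping exons are
rejected outright rather than merged, because the skipping combinatorics
assume disjoint exons. Transcripts sharing an exon chain are not collapsed
before enumeration; deduplication happens at the junction level, where it
is equivalent and simpler.

## Junction library

For a k-exon transcript the library holds the k−1 known junctions and all
(k−1)(k−2)/2 exon-skipping junctions (exon i joined to exon j, j ≥ i+2,
skipping j−i−1 inner exons). Both counts are validated against a
brute-force enumeration of all exon pairs in the test suite. Flanks of up
to L bases per side (L configurable; 50/75/100/150 are the conventional
choices, matching common read lengths) are spliced in transcript
orientation; minus-strand records are reverse-complemented so reads from
stranded libraries align directly. A flanking exon shorter than L yields a
truncated flank, so the per-record flank lengths — not L — define the
fusion point (local position `up_len`), and the breakpoint map back to
genomic coordinates is an explicit bijection onto the two flank intervals.
When the same (chrom, strand, donor, acceptor) key arises as an adjacent
pair in one transcript and a skip in another, the record is categorized
known: a junction already present in the known set is never double-counted
as novel.

## Junction quantification

An alignment supports a junction iff one gapless aligned block covers the
two bases either side of the fusion point and at least `min_anchor`
(default 8 bp — a conventional spliced-alignment anchor; the underlying
data gives no rule, so it is a flag) aligned bases fall on each side.
Reads with an insertion or deletion at the fusion point are rejected as
non-spanning because their breakpoint is ambiguous. Secondary and
supplementary alignments are ignored; a read counts at most once per
junction; reads spanning several records count for each (the multi-hit
fraction is reported, and a unique-only mode removes them). The audit
tallies satisfy counted + non_spanning + short_anchor + unmapped = records
examined on every input.

## Poly(A) sites

A read qualifies as a poly(A) tag iff its maximal uninterrupted terminal
A-run is ≥ `min_tail` (default 6) and the remaining prefix is ≥
`min_trimmed` (default 15). An exact run is the simplest reproducible
definition of "a terminal stretch of A"; allowing mismatches would need an
error model the data does not provide. Trimmed-tag 3′-most aligned bases
(reference_end−1 on +, reference_start on −) are clustered by
single-linkage within `cluster_window` (default 10 bp, reflecting the
micro-heterogeneity of cleavage); the representative is the modal
position, ties broken 3′-ward. PAS annotation scans the transcribed-strand
sequence of the `search_window` (default 40 bp, generous around the
canonical 10–30 nt placement) bases upstream: table hexamers are tried in
published human frequency order and the first ranked hit wins regardless
of proximity; among occurrences of that hexamer the one nearest the
cleavage site is reported. The search runs on genomic sequence rather than
read sequence — robust to sequencing errors; the alternative would tie the
annotation to per-read quality. The table (canonical AATAAA + 10 variants)
ships as a replaceable TSV data file. A-rich downstream genomic sequence
(fraction of A > 0.7 in 10 bases) flags probable internal priming but does
not filter, so no genuine site is silently lost.

## Exon trios and inclusion ratios

Every consecutive exon triple of every transcript forms a trio
("all possible exon trios" is read as all consecutive triples — the
alternative reading, triples sharing flanks across isoforms, would create
events no single annotated isoform supports); identical triples from
different transcripts merge. The inclusion ratio is the length-normalized
density ratio IR = (n_inc/len_inc) / (n_inc/len_inc + n_skip/len_skip); a
binomial standard error sqrt(IR(1−IR)/(n_inc+n_skip)) accompanies the
point estimate. This deliberately replaces a Bayesian posterior with the
ratio definition itself plus a frequentist error bar. The coverage cutoff
max(n_min, ⌈ρ·middle_len/read_len⌉) with defaults n_min=4, ρ=2 makes the
required evidence grow with the middle exon (a 300 bp exon at 100 bp
reads needs 6 reads; a 50 bp exon falls back to the floor of 4).
Read-to-isoform support counting is the caller's job (counts in, estimate
out); the bundled `classify_support` implements the simplest consistent
rule — a read supports skipping iff it splices the two flanks together,
inclusion iff it touches the middle exon or either inclusion-only
junction.

## Gene counting

`assign_read` evaluates the intersection_nonempty rule with interval
arithmetic rather than per-base loops: the genes overlapping every covered
position are exactly those whose coverage of the read equals the union of
all genes' coverage, which the tests verify against a literal per-position
oracle on randomized fixtures. Mates of a pair merge into one fragment
(union of blocks) and count once; multi-mapped alignments (secondary, or
mapq 0 with NH > 1) are tallied separately and excluded, since the
downstream count test assumes one observation per fragment.

## Differential tests

The 2×2 chi-square uses the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))
with 1 df and no continuity correction; tables with an expected cell < 5
are tested but flagged. Replicates within a condition are pooled (summed)
before testing. The count test is a conditional NB exact test: under the
null both condition sums share a common per-unit rate q̂ = (k_A+k_B)/(s_A+s_B)
estimated from the size-factor totals; each sum is modelled NB with mean
μ_c = q̂·s_c and variance μ_c + α·Σ_j(q̂·s_cj)² — shot noise plus
overdispersion — and the two-sided p sums all splits of the observed total
no more probable than the observed one. Dispersion α is method-of-moments
per feature across within-condition replicates (shot-noise term subtracted
using the mean reciprocal size factor), deliberately left unclipped so the
expression-binned trend (≥ 20 features per bin) is unbiased; the working
value is the per-feature maximum of own estimate and trend, a conservative
sharing rule protecting features whose replicate variance is understated
by chance. Without replicates the cross-condition estimate stands in,
fully pooled by expression bin — usable but low-powered, and the variance
then absorbs any true condition effect. BH adjustment is applied per
analysis family (genes, junctions, poly(A) sites, trios), since each is
its own multiple-testing problem. Observed calibration at the defaults
(3v3, 200 Poisson-null features): rejection at the 5% level stays inside
the exact binomial interval, slightly conservative, as expected of a
discrete exact test; empirical FDR under a 4-fold-change mixture sits near
the nominal level.

Note that BH step-up adjustment is *not* idempotent in general (adjusting
(0.5, 1.0) yields (1.0, 1.0)); the properties that do hold — monotone in
sorted order, never below the input, re-adjustment never decreasing — are
the ones tested.

## Synthetic fixtures

The simulator emits a random chromosome with 6 multi-exon genes
(3–6 exons of 120–300 bp, introns 80–400 bp) on both strands, 100 bp
error-free reads by default (1,200 per run: 50% unspliced exonic, 35%
junction-spanning with anchors ≥ 8, 15% poly(A)-tailed with 8–12 A and the
canonical PAS planted 15–30 bp upstream of each cleavage site), and SAM
records synthesized directly from the known placements — no aligner runs,
so alignment error is excluded by construction. Trio support is simulated
at count level: 2,000 reads per trio split binomially with
length-proportional weighting around true inclusion fractions
ψ ∈ {0.1, 0.5, 0.9}, which the IR estimator should (and does) recover
within 3 standard errors. Differential calibration uses separately
simulated NB matrices (3v3, mean 100, α ∈ {0, 0.1}). All sizes are chosen
so the whole suite and the acceptance script run in seconds while every
count-level property is still exactly checkable.

What passing these fixtures does *not* show: robustness to real aligner
behaviour (soft-clipping, mismapping near junctions), non-uniform
coverage, internal priming at genomic A-stretches (flagged but never
exercised as a confounder), PCR duplicates, or annotation errors. The
error-rate knob degrades reads uniformly at random, which is a far milder
corruption than real base-call error profiles.

## Degenerate inputs and tie-breaks

Zero-count trios have undefined IR and fail the cutoff rather than
reporting 0 or 1. Zero-margin 2×2 tables raise instead of returning p = 1.
Size factors require a feature positive in all samples; the
pseudo-reference fallback (positive-entry geometric means) is opt-in
because it changes the estimand. Cluster ties at equal multiplicity break
toward the 3′-most position, the biologically latest cleavage. PAS windows
truncated by a chromosome edge shrink with a logged warning.
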