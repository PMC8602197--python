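# Methods

## Overview

`salviacirc` implements a desk-scale circRNA discovery and characterization
pipeline of the kind used for non-model plant transcriptomes: rRNA-depleted,
RNase-R-treated RNA-seq of several tissues is screened for back-splice
junctions with two independent callers, their per-sample intersection forms
a consensus set, and the cross-sample union becomes the circRNA catalog
that is then classified, quantified, tested for differential expression,
correlated with parent genes and co-expression modules, scanned for miRNA
binding sites, and checked by convergent/divergent primer logic.

Because real datasets of this kind are tied to a specific genome assembly
and sequencing run, the package ships a first-class synthetic-data module
that generates the entire study — genome, annotation, planted circRNAs,
tissue design and reads — so every downstream stage can be validated
against a known truth.

## The synthetic study

`simdata.simulate_genome` draws uniform-random scaffolds and lays out
non-overlapping multi-exon genes left to right with intergenic gaps of at
least 500 nt (also at scaffold edges). Exon lengths are 300–400 nt and
introns 150–250 nt; these defaults keep ten 3–8-exon genes comfortably on
a 50 kb scaffold while leaving introns long enough to host intronic
circles and exons long enough that a 150 nt read fits inside one exon.

`plant_circrnas` plants the three circRNA classes: exonic circles span 1–5
consecutive exons of one gene with both ends on exon boundaries (their
circular sequence is spliced), intronic circles lie strictly inside one
intron, intergenic circles overlap no gene. All circles are at least
160 nt so a 150 nt read never wraps a circle more than once.

**Junction identifiability.** Planted junctions are required to be
*unambiguous*: the genomic base immediately after `end` must differ from
the circle's first base, and the base immediately before `start` from its
last base. If either matched, the back-splice at `(start, end)` would
produce exactly the same reads as one at `(start±1, end±1)` — in real
genomes this ambiguity is resolved by GT/AG splice signals, which a
uniform-random genome does not provide. The constraint costs roughly 44%
of candidate placements and makes "exact-coordinate recovery" a
well-posed requirement.

`simulate_reads` emits, per sample, (a) back-splice junction read pairs
for each circle — mate 1 is an end-flank + start-flank concatenation of
the circular sequence crossing the junction with at least the anchor
length (20 nt) on each side, confined to the junction-flanking exons for
spliced circles; mate 2 is a reverse-complemented window of the circle
that never touches the junction — and (b) linear-transcript pairs from
spliced gene models, thinned by the RNase-R retention fraction (default
0.05). Junction-read counts are negative-binomial with variance
mu + phi mu^2 (phi default 0.2) around abundance x tissue multiplier;
`min_junction_reads` optionally floors the draw for guaranteed-coverage
designs. Base qualities are Q37, with Q12 at substitution errors.
Everything is deterministic per seed.

Per-circle abundances are log-normal around a base mean of 8 expected
junction reads; half of the circles (and, independently, half of the
genes) are tissue-specific with a 4x boost in one random tissue. These
are stipulations — abundance distributions for plant circRNAs are not
settled — chosen so that tissue-pair differential expression has both
true positives and nulls at the default design.

What the generator does **not** emulate: instrument error profiles, PCR
duplicates, rRNA carry-over, intron retention, three-segment chimeras,
GC bias, or real splice-site sequence context. Passing tests therefore
demonstrate algorithmic correctness on an idealized substrate, not
end-to-end performance on real libraries.

## Back-splice detection

Reads are first QC-filtered exactly as in the standard recipe: a read is
discarded when more than 50% of its bases are below Q20 or more than 5%
are N, and the surviving mate goes with it.

**Split-segment caller** (`detect_split`). The genome is indexed by exact
20-mers. For each read (both orientations) the prefix and suffix anchors
are located and extended ungapped; a junction `(start, end)` is supported
when the prefix maps ending at `end`, the suffix maps beginning at
`start`, on one scaffold in reversed genomic order, with both segments at
least 20 nt and span at most 100 kb. A read contributes one count per
junction; junctions with at least `min_reads = 2` counts are reported.
Anchor length 20 and the 100 kb span ceiling are this package's choices
(real callers inherit their own defaults); they are logged in output.

**Realignment caller** (`detect_realign`). Candidates are the split
caller's seeds (at one supporting read) plus every exon-boundary pair of
every gene — making the two callers overlapping but distinct, which is
what per-sample intersection statistics require. For each candidate a
junction pseudo-sequence is built (end-flank + start-flank, 130 nt each,
exon-spliced when both candidate ends fall in exons of one gene) and
reads are counted that align ungapped across the midpoint with >= 20 nt
on each side and <= 2 mismatches.

Both callers are exact-match tools by design: substitution errors reduce
split-caller sensitivity (the realign caller tolerates 2 mismatches), and
no gapped or general-purpose spliced alignment is attempted.

## Consensus and catalog

Per sample, the consensus is the coordinate-exact intersection of the two
callers (a `--slop` tolerance exists for real data but defaults to 0);
the report carries |A|, |B|, |A∩B|, |A∪B| and the intersection/union
ratio. Consensus read counts come from the realign caller (the deeper
counter); a `max` policy is selectable. `merge_samples` unions consensus
sets across samples by coordinates, preserving per-sample counts and
provenance, and `sharing_stats` produces intra-group (replicate) sharing
and pair/triple Venn region counts.

## Classification and alternative circularization

A junction is **exonic** when both ends fall in exons of a single gene
(ties go to the tightest-span gene), **intronic** when the whole interval
lies inside a single gene without being exonic by that rule, and
**intergenic** otherwise; ends overlapping two different genes with no
common host are intergenic with a warning. Mixed exon/intron ends are
intronic under this default; because field practice varies, a
`mixed_ends="exonic"` policy and a `boundary_slop` are exposed as options
rather than hard-coded. Spanned exons are counted over the interval, and
the position category (first / middle / last / first_and_last) is
computed in transcript orientation, so minus-strand genes flip genomic
order. Alternative circularization groups exonic circles by parent gene
and reports the genes-producing-k-circles histogram.

## Quantification and differential expression

RPM is junction reads per million total sequencing reads; FPKM is
fragments per kilobase of merged exonic length per million mapped
fragments. Fold changes are ratios of replicate-mean RPM with a 0.01 RPM
pseudocount on both sides (zero-count features are otherwise undefined;
the choice only matters for features near zero).

The significance test is a **conditional binomial count test**: pooling
replicates within each tissue, x_A ~ Binomial(x_A + x_B, pi0) under the
null, with pi0 the pooled library-size share of tissue A; p-values are
two-sided (minimum-likelihood method) and adjusted by Benjamini-Hochberg
within each tissue pair. This test was chosen because it is exact,
dependency-free and well calibrated for junction counts; it deliberately
does not model biological overdispersion (a negative-binomial GLM is out
of scope), so its p-values are conditional on the pooled counts. Calls
require |log2FC| >= 1 and q <= 0.05 — the fold-change gate makes the
procedure conservative, which the null-calibration test quantifies
(<= 1% of null features pass both gates at the default design).

Expression heatmap profiles are per-feature Z-scores over tissue-mean RPM
(population variance, so rows have mean 0 and variance exactly 1),
clustered with Euclidean distance and average linkage; the feature tree
is cut into k clusters (default 5).

## Co-expression and enrichment

circRNA/parent-gene correlation is Pearson r over shared samples (the
replicate-level 9-sample layout by default, not tissue means) with the
two-sided t-based p-value; sig_pos/sig_neg at |r| >= 0.5, p < 0.05.
Module co-expression takes modules as *input* (module detection is a
separate concern and is not re-implemented); each module's eigengene is
the first principal component of its gene-wise standardized expression,
sign-oriented to correlate positively with the module mean, and every
circRNA is tested against every eigengene at |r| >= 0.9, p < 0.05.
Term enrichment is an upper-tail hypergeometric test against a supplied
background with BH adjustment; a term is significant at q < 0.05 with at
least 3 query genes in the term.

## miRNA binding sites

The scanner slides each miRNA over each circular sequence (padded across
the back-splice so junction-spanning sites are found and mapped back to
circle coordinates) and scores antiparallel complementarity with an
additive penalty: Watson-Crick 0, G:U wobble 0.5, mismatch 1.0, gap 2.0,
doubled at miRNA core positions 2–13 (5' numbering); at most one gap per
site (an inserted target base takes the core factor of the following
miRNA position); default reporting cutoff 5.0. Overlapping windows
collapse greedily to the best-scoring site, which makes the reported set
monotone in the cutoff. Hit lists from any such scheme depend on its
penalty table; this one is fixed and recorded in output headers. No
RNA-accessibility energy term is computed.

## Primer design and in-silico PCR

Primers (18–24 nt, Wallace-rule Tm 2(A+T)+4(G+C), pair difference
<= 4 °C) are drawn from genomically contiguous windows of the circular
cDNA, so a primer never crosses a splice or the back-splice. The
divergent pair faces outward on the genome (forward primer near the
circle's 3' end, reverse near its 5' start): its only product runs across
the junction on circular cDNA. The convergent pair faces inward; for
spliced circles with more than one exon segment the forward primer sits
in the first segment and the reverse in the last, so the genomic product
is strictly longer than the cDNA product whenever an intron is spanned —
the product-size window (100–400 bp) yields to this constraint for large
circles. Expected product sizes on circular cDNA, linear cDNA and
genomic DNA are computed by exact-match in-silico PCR (both strands,
single-lap circular search, 5 kb cap), and each designed pair is verified
against the template logic of its orientation before being returned.
Templates under 80 nt are refused.

## Problem sizes and numerics

The test-suite and acceptance runs use a 5 x 50 kb genome with 30 genes,
30 planted circRNAs and a 3 tissue x 3 replicate design (~2,000 read
pairs per sample) — large enough to exercise every code path with exact
truth accounting, small enough to finish in seconds. Coordinates are
1-based inclusive everywhere except BED export (0-based half-open).
Ties are broken deterministically (coordinate order for junctions,
lexicographic ids elsewhere); all randomness flows from a single integer
seed through `numpy.random.default_rng`.

## Known limitations

- The callers assume substitution-only errors and unique 20-mer anchors;
  repetitive genomes and indel errors are out of scope.
- DE p-values ignore replicate-level overdispersion by construction.
- The miRNA penalty scheme and cutoff are package-defined; absolute hit
  counts are not comparable across scoring schemes.
- Classification of mixed exon/intron junctions and boundary tolerance
  are policy options, not empirical truths.
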