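# Methods

This note documents the procedures implemented in `pairqc`, the defaults
and conventions chosen where several reasonable designs exist, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Coordinates and the unit of processing

All internal coordinates are 0-based half-open; conversion happens only at
file boundaries (GTF and SAM positions in, wiggle and GFF-like positions
out). The unit of processing is the read pair. Records are paired by
name — adjacently for name-sorted input, through a bounded name-keyed
cache (default 2·10⁶ records) for coordinate-sorted input — and the two
presentations of the same records yield identical pair multisets.
Secondary and supplementary records are tallied and never paired; leftover
single records are tallied as orphans. The retention filter then drops a
pair when either mate is unmapped, secondary, supplementary, or below the
MAPQ threshold (reason precedence in that order). The MAPQ default is 50,
which excludes multi-mappers under the MAPQ conventions of the common
spliced aligners without being tied to any one of them; it is
configurable (`--min-mapq`). Duplicate-flagged reads are retained unless
`--drop-duplicates` is given. Single-end data is out of scope: orphans
are counted, never processed.

A pair's **footprint** is the union of both mates' M/=/X reference bases;
D- and N-spanned bases are excluded and mate overlap is counted once.
Pairs whose mates map to different chromosomes have no single footprint
and are tallied `_unassignable` (counting) / `ambiguous_region` (region
rates).

## Cycle space

All per-cycle metrics use *as-sequenced* cycles, 1-based: a reverse-strand
alignment stores the reverse complement of what the sequencer read, so its
sequence, qualities and CIGAR are flipped back before cycle indexing. A
sequencer-side artifact at machine cycle c then appears at cycle c
regardless of alignment strand. D and N CIGAR ops consume no query; their
events are recorded at the boundary between the flanking query cycles,
indexed by the preceding cycle. Clipped-sequence nucleotide composition is
indexed by signed offset from the clip boundary (lead clips −1, −2, …
backward; tail clips +1, +2, … forward); indexing from the boundary rather
than the read end keeps clips of different lengths aligned with each
other.

Quartiles of per-cycle quality histograms use the lower-quantile
convention (the smallest value whose cumulative count reaches ⌈q·n⌉),
which is deterministic and exact on integer phred scores.

## Annotation processing

The GTF reader consumes `exon`, `CDS` and `UTR`/`five_prime_utr`/
`three_prime_utr` features with Ensembl-style attributes; other features
are ignored. Exon flattening merges same-strand genes whose exons overlap
by ≥1 bp (transitively, via union-find) into aggregates named
`A+B`; within an aggregate, parts are the disjoint segments of the exonic
union cut at every exon boundary of every member transcript, numbered by
genomic start (`A+B:E001`, …). Opposite-strand overlap never merges;
unstranded (".") genes are treated as "+" for merging, with a logged
warning — the behaviour of opposite-strand overlap in unstranded
libraries is inherently ambiguous, so we log rather than guess. Annotated
junctions are the distinct (chrom, strand, intron) triples over all
adjacent exon pairs within transcripts.

Region classes are maintained as disjoint unions with precedence
CDS > UTR > other-exon > intron > intergenic. A pair is classified by the
majority class of its footprint bases, ties going to the
higher-precedence class (the rule is ours; only the metric itself is
standard).

## Counting rules

Gene assignment is the union rule on pairs: the union over all footprint
bases of the exon-overlapping gene sets; exactly one gene retains the
pair. In stranded modes the gene sets are restricted to genes on the
protocol-resolved fragment strand (read 1's strand under a second-strand
protocol, its opposite under first-strand). Exon-part counting requires an
unambiguous assignment at *aggregate* granularity and then increments
every part of that aggregate touched by ≥1 footprint base — a pair may
increment several parts, once each; ambiguous pairs increment nothing
(no fractional counting). Junctions are counted per pair: a junction
observed in both mates counts once. Known matching is exact-boundary with
strand compatibility (an unstranded observation matches either annotated
strand and is recorded under the annotated locus); no fuzz window. Loci
with ≥4 supporting pairs are "high coverage" by default
(`--junction-high-threshold`). All annotated junctions are listed in the
count table even at count 0.

Insert size is computed from the outer span of the mates minus N-skipped
reference within either mate and minus annotated introns *fully contained*
in the inter-mate gap. Introns only partially overlapping the gap are not
subtracted — a deliberate, deterministic rule that covers the common
spliced-fragment case; fragments whose inter-mate gap ends inside an
intron are therefore overestimated by the residual intronic bases. Mates
on the same strand, different chromosomes, or in invalid orientation are
tallied unassignable and excluded from the histogram.

Strandedness calls use r = fwd/(fwd+rev) over pairs overlapping exactly
one stranded gene: r ≥ 0.9 second-strand, r ≤ 0.1 first-strand,
0.4 ≤ r ≤ 0.6 unstranded, otherwise indeterminate; at least 1000
informative pairs are required. Thresholds are configuration defaults,
not inferences.

Gene-body coverage maps each gene's exonic union onto 40 equal-width
relative-position bins, 5′→3′ (reverse-strand genes flipped), and
accumulates footprint depth from assigned pairs; genes shorter than 40
exonic bases are excluded. Expression strata are quartiles of the
per-gene pair counts among genes with ≥1 pair: top quartile high, bottom
quartile low, middle half medium.

## Tracks

Wiggle output is fixedStep with step = span = window (default 100 bp),
1-based starts, one declaration per chromosome; the last partial window is
kept. Values are raw footprint-base counts per window; normalization is
applied only in multi-sample summary tracks, where the default per-sample
factor is 10⁶ / retained-assigned-pairs and the output is the mean of the
scaled inputs. Junction BED scores are capped at 1000 for format
compatibility, with the true count preserved in the name field. Stranded
runs emit `.fwd`/`.rev` track pairs keyed by the protocol-resolved
fragment strand.

## Single-pass architecture

One traversal of the alignment stream feeds every accumulator; metric
tables, count files and tracks are all emitted at the end of the same
pass. Disabling a sub-function (`--skip metrics|counts|tracks`) omits its
output files and changes nothing else — the remaining outputs are
byte-identical, which the test suite verifies by comparison against
isolated runs. Metric tables are tab-separated with a one-line
`# generated-by` comment carrying the tool version and key parameters,
deterministic row order, and no timestamps, so identical inputs give
identical bytes.

## Report

The decoder is a tab-separated table with `unique_id` (unique),
`qc_dir`, and optional `sample_id` / `lane_id` / `group_id` columns
defaulting to `unique_id`. The default battery is 34 panels: per-read
quality, NVC (raw / unclipped / clipped), N-rate, clipping, CIGAR
profiles and lengths (2 each = 16), insert size, GC, strandedness,
mapping locations, four gene-body strata, gene diversity, assignment
categories, four junction-locus classes, two junction-event classes,
per-chromosome rates and drop-reason rates. The count of 34 is fixed by
the default manifest; the composition is this package's own and is
overridable in code. Colors are assigned to sorted grouping levels from a
fixed palette; within a level replicates get distinct markers and
horizontal offsets. Rendering reads only the metric tables, and vector
output (SVG/PDF) is byte-reproducible: the SVG hash salt is pinned and
PDF creation/modification dates are stripped.

## Synthetic data generator

The generator emulates a paired-end RNA-seq experiment at desk scale:
multi-exon genes on both strands with configurable overlap fraction and
optional exon-skipping second transcripts; a random genome with
configurable GC; expression-weighted fragment sampling with near-normal
fragment lengths (mean 180 bp, sd 30, clipped to [read length, transcript
length]); spliced alignments with correct N ops; per-cycle quality decay
(mean 38 → 30 over the read); optional soft clipping, 3′ exponential
positional bias, and the three strand protocols. The sequencer-fault
model N-truncates a seeded fraction of one mate from a given cycle onward
and soft-clips the alignment over those cycles, reproducing the
signature of a mid-run scanner fault. Default scale is 20 genes and
10,000 pairs of length 75, which runs in seconds on one CPU; that scale
is also what the acceptance script uses.

The generator writes alignments directly rather than running an aligner,
so it exercises alignment *consumption*, not alignment production. It
does not model substitution/indel sequencing errors (beyond
N-substitution), PCR duplicates, multi-mapping, reference bias, or
quality-score miscalibration — passing tests therefore demonstrate
correctness of the accounting and the metric definitions on structurally
realistic input, not robustness to every real-data pathology.

## Numerical and degenerate-input choices

Empty inputs produce empty-but-valid outputs (all-zero gene-body matrix,
empty diversity curve flagged in the summary, NA rows for cycles with no
observations). GC fraction excludes N from numerator and denominator;
all-N pairs are skipped and tallied. FPKM with zero assigned pairs is NA
with a warning. Gene-diversity ties are broken by gene id; all row orders
are deterministic.

## Known limitations

- Single-end libraries are not processed (orphans are only tallied).
- The insert-size intron rule (full containment) overestimates fragments
  whose gap boundary falls inside an annotated intron.
- Known-junction matching is exact; a one-base aligner wobble produces a
  "novel" locus.
- CRAM input and bigWig/tabix outputs are not supported; tracks are
  plain-text wiggle/BED.
- Novel junctions are per-replicate; no cross-sample merging of novel
  loci into a combined annotation is attempted.
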