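# Methods

## Scope and model

`foldscan` treats a genome as (1) a set of simple-repeat annotations
(consensus unit, copy number, span, similarity, source track) and (2) raw
sequence. Five computations are layered on this: composition
classification of repeats, single-linkage clustering of CG-rich
trinucleotide repeats (TNRs) into loci, an expected/observed
representation statistic for repeat–feature co-occurrence, windowed
composition tracks, and an exact-match pseudoread mappability probe. All
coordinates are 0-based half-open throughout (the UCSC/BED convention of
the source tables).

## Repeat catalogue

Composition is computed on the **consensus unit**, not the realized
genomic sequence, because the annotation databases' defining field is the
consensus; a flag on `locus_gc`/the profile tools covers realized-sequence
composition when needed. N bases count in the denominator and in neither
numerator (conservative: an ambiguous unit is harder to classify, never
easier). The classification rule is

* CG-rich iff (#C+#G)/|u| ≥ *t*, else AT-rich iff (#A+#T)/|u| ≥ *t*,
  else other; *t* = 0.60 by default. With *t* > 0.5 the two classes are
  mutually exclusive. Unit lengths outside 1–14 bp are dropped.

Concatenation merges runs of Tandem-Repeat-Finder/microsat records that
continue the same repeat chain: same unit up to rotation (units are
normalized to their lexicographically minimal rotation, because TRF
reports arbitrary phase) and inter-record gap ≤ `max_gap` (default 0,
i.e. abutting records only). Strand is **not** folded: CGG and CCG remain
distinct classes; both folded and unfolded counts can be derived from the
catalogue since the unit is carried verbatim. Merged records get
copies = span/period and span-weighted mean similarity. RepeatMasker
records pass through unmerged — the TNR analysis uses them as annotated.

TNR identification takes the period-3 subset, restricted by default to
RepeatMasker-sourced records (`tnr_source_rmsk_only`). For `rmsk` tables
only `repClass == "Simple_repeat"` rows are treated as simple repeats;
Satellite inclusion is a flag (default off). Records duplicated across
source tracks (same interval and normalized unit) are kept once,
preferring the RepeatMasker copy.

## Clustering

`cluster_tnrs` chains genome-sorted records whose successive gaps are
≤ `max_gap` (single linkage). The gap is a required parameter with a
suggested default of 10,000 bp, chosen so a BAC-scale locus (~150–200 kb)
forms a single cluster; there is no canonical definition of "cluster" in
the annotation, so the default is a modelling choice, and results should
be read as a function of the gap. Clusters are ranked by member count,
ties broken by genomic position for determinism.

## Enrichment statistic

With repeats *r₁..rₙ*, features *f₁..fₘ*, genome length |G|:

* expected = (Σ|rᵢ| · Σ|fⱼ|) / |G|²
* observed = (Σⱼ Σᵢ |rᵢ ∩ fⱼ|) / |G|
* statistic = log₂(observed/expected), undefined (reported missing) when
  either term is 0.

Spans are **raw sums** of record lengths exactly as the formulas read —
overlapping records within one set double count; a `merged_spans` flag
switches both terms to union lengths for sensitivity analysis. Overlap is
intersection length with a 1 bp criterion (touching half-open intervals
share nothing). Genome length defaults to the full FASTA length including
N runs. Cross-pair overlap uses an interval tree per chromosome; the
quadratic enumeration exists only as a test oracle. The log base is
configurable (default 2). No significance test is attached by default —
the statistic is descriptive; an optional shift-permutation p-value
(circular per-chromosome shifts of the repeat set, seeded) is provided
for users who want one.

Calibration: under uniform independent feature placement observed ≈
expected, so the mean log₂ fold change over replicates is ≈ 0 — but the
log of a ratio is biased downward when the per-replicate overlap mass is
small (Jensen). The calibration suite therefore uses a layout with ~50+
expected overlapping pairs per replicate; with sparse overlap the
per-replicate statistic is noisy even though the ratio's expectation is
still 1.

## Composition profile

GC tracks tile each chromosome with fixed windows (default 100 bp for the
bedGraph, 1,000 bp for quantification); the final window is truncated, so
tilings are exact partitions. N bases depress GC% (denominator = window
length); `exclude_n` switches the denominator to non-N bases. Motif scans
(CpG; GCC/GGC) are forward-strand only: CpG is strand-symmetric and the
GCC/GGC pair jointly covers both strands of the GCC pattern. Overlapping
occurrences all count. A motif is assigned to the window containing its
start coordinate, so boundary-straddling motifs count once (left window);
this assignment is a fixed, documented choice. 2D histograms use uniform
bins on [0, max] per axis with out-of-range values clipped into the last
bin (not discarded), so histogram totals always equal window counts.
`longest_unit_run` reports the maximum k with unitᵏ a substring,
checking every phase, and quantifies how interrupted a repeat tract is.

## Mappability probe

"Mappability" is defined as exact-match L-mer uniqueness with strand
folding: a pseudoread (default L = 100, step 1) is *unique* if its
sequence or reverse complement occurs at exactly one genomic site, *multi*
at ≥ 2; each genomic position contributes one strand-folded occurrence,
so a palindromic read at a single site is unique. Reads containing N are
not classifiable by exact match and are excluded from the unique/multi
denominator, reported separately. This deliberately is not
alignment-score mapping: the question it answers is whether the sequence
content is re-identifiable at all, which exact uniqueness captures
deterministically; the FASTQ export (constant maximal quality — the reads
are error-free reference copies) lets users replicate the question with a
real aligner. The implementation indexes the queried L-mers once and scans
the genome in a single pass. The default probe region around a locus adds
10 kb flanks.

## Synthetic genomes and what they show

Backgrounds are i.i.d. bases with P(C)+P(G) = `background_gc`
(default 0.41, the human genome-wide mean); repeats are embedded verbatim;
interruption rules insert a base after every *k* units so the longest
in-phase run equals *k*. One seeded stream drives chromosome backgrounds
(in declaration order) then feature placement (in list order), making
bundles byte-reproducible. `near_repeats` placement samples feature starts
within ± distance of a random repeat midpoint, creating tunable true
enrichment. Emitted `simpleRepeat` rows mirror the embedded repeats
exactly; period-3 repeats also get `rmsk` rows and ≥15-copy dinucleotide
repeats get `microsat` rows, mirroring which real tracks carry which
annotations.

The default benchmark (`build_benchmark_spec`) is a ~4.35 Mb
three-chromosome miniature of the human simple-repeat landscape, with
these facts planted as inputs: 12,600 AT-rich repeats vs 420 CG-rich
(30×), AT-rich TNR copy numbers spanning 1–161 and CG-rich 1–332 (the
332-copy record is an uninterrupted CGG tract, the FRAXA analogue), and a
333-member CGG cluster on the chr2 analogue whose 6 bp inter-record
spacers (2 A/T + 4 G/C each, randomly arranged) give the locus exactly
8351/9015 = 92.6 % GC and keep its longest contiguous CGG run at the
central record's 17 units. Tests verify the pipeline *recovers* these
planted values from the emitted FASTA and tables alone.

What passing on synthetic data does **not** show: real annotation tables
contain messier consensus calls, nested and overlapping records,
assembly gaps, and satellite arrays the i.i.d. background lacks; real
feature databases overlap each other internally; and real hg38 inputs are
~700× larger. The pipeline streams tables and uses interval indexes, so
scale is a matter of runtime, not algorithm, but the synthetic results
validate correctness of the computations, not the biology of any
particular genome.

## Numerical and degenerate-input choices

* Thresholds compare with ≥ (a unit at exactly 60 % C/G is CG-rich).
* Empty inputs: empty catalogues, feature sets and windows are legal and
  produce empty outputs; `unique_fraction` is 0 when no read is
  classifiable; copy ranges of an empty class are reported as missing.
* bedGraph values use fixed 2-decimal formatting; summary JSON uses
  sorted keys — outputs are byte-stable for identical config + seed.
* Cluster ranking, catalogue ordering and table emission all use total
  orders (position, then size) so no output depends on dict/hash order.

## Problem sizes

The bundled study conditions (~4.35 Mb genome, ~13k repeat records, 800
features, 29k pseudoreads at step 1) run the full pipeline in a few
seconds; calibration suites use 200-replicate batches on 200 kb genomes.
These sizes were chosen to make the statistical checks (3-SE composition
bounds, ±0.1 null calibration) well-powered while keeping the whole suite
fast to iterate on.
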