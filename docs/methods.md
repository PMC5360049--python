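# Methods

This note documents the models, conventions and numerical choices behind
`stakit`, and what the simulator does and does not emulate.

## Read model and tail clipping

A library molecule is `5'-[TSO adapter][insert][A-tail][primer/adapter]-3'`;
sequencing from the adapter end yields the insert followed by however much
of the tail fits in the read. The clipper therefore works from the 3' end
of each read:

* **tail** = maximal 3'-terminal run of `A`. By default the run tolerates
  zero interruptions; `max_interruptions=k` allows up to `k` isolated
  non-A bases inside the run, each flanked 5'-ward by another A, so an
  interruption can never sit at either boundary of the run. `N` never
  counts as `A` (conservative: an uncalled base is not evidence of tail).
* **selection**: tail length ≥ `min_tail` (default 9, i.e. "more than
  eight As"). This is the strictest reading of that rule; the historical
  clipper's mismatch tolerance is unknown, hence the option rather than a
  guess.
* **insert filter**: clipped inserts shorter than `min_insert`
  (default 18) are dropped. The value is imported from the downstream
  aligner's minimum-match setting so that unalignable reads never reach
  the aligner.

Qualities are clipped in lockstep; no quality-based trimming is performed.
Two documented consequences: (i) with zero interruptions an emitted insert
never ends in `A`, so re-running the clipper on clipped output discards
everything — intentional, and asserted in tests; (ii) a molecule whose
genomic 3' end is adenosine has those bases absorbed into the tail — the
chemistry genuinely cannot distinguish terminal-A isoforms from tail, and
the toolkit does not pretend otherwise.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open on a stranded interval
type; GTF/GFF3 are converted on ingestion, BED is taken as-is, and
bedGraph output is emitted in the same convention, making file round-trips
bit-exact. Merging treats book-ended intervals as one block. Subtraction
is strand-aware with `.` as a wildcard on either side. Derived layers:

* **introns** = transcript span − merged exons, per transcript, then
  unioned across transcripts (the definition is per-transcript because a
  base can be exonic in one isoform and intronic in another; the union is
  what the intron *layer* needs).
* **non-mature miRNA** = merged primary transcripts − merged mature arms,
  per chromosome and strand.

Exons of all transcripts of a gene are merged per gene, since counting is
at gene level. Strandless BED records (tRNA/repeat tracks often omit
strand) are indexed on both strands rather than silently dropped; this is
the permissive reading of "strandedness was taken into account" for rows
where no strand exists.

## Assignment

Priority is exon > intron > tRNA > repeat; the first layer with a
same-strand overlap of ≥ `min_overlap` (default 1) bases wins, and reads
matching nothing on their own strand are unannotated — including reads
exactly antisense to annotation, consistent with forward-stranded
chemistry (the clipped insert is sense to the transcript; a `strand_mode`
option exists because conventions vary). The alignment footprint is the
reference span (splice gaps included), matching interval-overlap tools.
Only primary alignments are accepted; callers must filter.

Category counting is once-per-read (so category percentages are exact
fractions of aligned reads); gene counting is multicov-style
(once-per-overlapped-gene). Both conventions are deliberate and
documented side by side. Biotype ties — an exon read overlapping genes of
two biotypes — go to the larger overlap, then the lexicographically
smaller gene id: deterministic, and affecting only constructed overlap
cases.

`filter_summed_counts` keeps rows with strict `sum > threshold`; the
boundary case (sum exactly equal) is dropped, matching the strict reading
of "summed counts > N".

## Mature miRNA

Reads with ≥ 1 base of same-strand overlap with the non-mature region are
removed (the intersect-default), then survivors are counted per mature
arm with any-overlap semantics; a containment flag is provided because
the historical choice between any-overlap and full containment is
unrecorded. Counts are keyed by accession, falling back to name. Two
invariants pin the construction: when arms tile the whole precursor the
remove step is a no-op and the pipeline equals direct counting; enlarging
the mature set can only shrink the removed-read count.

## QC

Gene-body coverage: per-base same-strand depth over each transcript's
exonic body (≥ 100 exonic bases; shorter bodies are binning noise),
oriented 5'→3', rescaled to 100 percentile bins by `floor(i·100/L)`,
summed over transcripts and normalized to 1. Aggregation is
coverage-weighted (transcripts with more reads contribute more), matching
the convention of the standard gene-body QC tools. RPM tracks multiply
per-base depth by 10⁶/aligned-reads and are written per strand with
lexicographic chromosome order and fixed 6-decimal values, so reruns are
byte-identical; conservation (Σ value·length = 10⁶·aligned-bases/aligned-
reads) is asserted in tests. The composition report embeds raw counts
next to every fraction and refuses mismatched library ids.

## Simulator

The generative model per molecule: draw an RNA class from `class_mix`,
then a source feature uniformly within the class.

* **short classes** (miRNA arms 22 nt, snoRNA 70 nt, tRNA 72 nt): the
  insert is the whole molecule.
* **anchored long classes** (mRNA, rRNA-like): the insert ends at the
  transcript 3' terminus and extends 5'-ward by `Geom(rt_dropoff_p)`
  bases (capped at the spliced length), modeling RT drop-off from the
  tail-anchored primer — this single mechanism produces the 3' coverage
  bias and the mRNA-fragment carryover seen in real tail-anchored
  libraries.
* **fragment classes** (intronic, repeat-derived): the 3' anchor is
  uniform within the feature (a cleavage product tailed where it was
  cut), with the same geometric extension.

A tail (default: constant 20 nt, the length encoded by a T₂₀V anchored
primer; the true post-tailing length distribution is a smear, so the
distribution is pluggable) is appended, the molecule is kept if the
insert lies in `size_window` (default 18–300 nt, emulating gel size
selection), optionally duplicated by a lognormal amplification weight
(σ = 0 by default, so reads = molecules and class fractions are exactly
binomial), and the read is the first `read_length` (default 50) bases of
insert+tail with i.i.d. substitution errors (default 10⁻³). Reads shorter
than `read_length` are emitted at natural length, as real post-trim reads
are.

Default `class_mix` (mRNA .07, snoRNA .03, miRNA .02, intronic .21,
tRNA .10, repeat .20, rRNA .37) was chosen so the simulated library's
category and RNA-type proportions resemble a low-input tail-anchored
total-RNA library: ~13 % exonic reads dominated by protein-coding
fragments, substantial intron/repeat/tRNA signal, and a large unannotated
share from rRNA absent from gene-model annotation — the rRNA-like locus
is deliberately left out of the toy GTF for this reason.

**Controls.** `pap_enabled=False` emits only mRNA-class reads (the one
class pre-adenylated in vivo); `rt_enabled=False` emits nothing. All
random draws are made for every molecule regardless of gates and size
selection, so toggling a control changes *which* reads appear but never
the content of the reads that remain — the simulated analogue of running
the same sample with an enzyme omitted.

**Truth.** Every emitted read records its molecule id, class, source,
tail and insert lengths, the genomic footprint of its read-covered insert
(what a perfect aligner would report) and its category under the bundled
annotation. `emit_truth_alignments` turns this into BED6 "perfect
alignments", which every downstream stage accepts in place of a BAM — the
default test path needs no aligner.

**Toy genome** (~100 kb, one chromosome, fixed seed): 10 three-exon
protein-coding genes (140 nt exons, 400 nt introns, alternating strands),
4 miRNA hairpins (80 nt precursors, 22 nt arms), 3 snoRNAs, 3 tRNA loci
(BED layer only), 6 intergenic repeats, one unannotated 1.5 kb rRNA-like
locus, plus two decorative constructions excluded from sampling pools: a
repeat inside an exon (assignment priority must make it invisible) and an
antisense gene over another gene's exon (strandedness must keep sense
assignment). The 3'-terminal base of every discrete molecule is forced to
a non-A so appended tails are exactly recoverable; fragment classes keep
random ends, as real cleaved RNA does.

## What the simulator does not model

No indels or structural errors, no polymerase-fidelity effects, no
template-switch artifacts, no UMIs (the chemistry has none), no
sequence-dependent tailing efficiency, and no multimapping — truth
alignments are unique by construction. Passing tests therefore
demonstrate the correctness of the *informatics* (clipping, set algebra,
priority, strandedness, normalization) under the stated generative model,
not robustness to alignment ambiguity or enzymatic sequence bias in real
data.

## Problem sizes and determinism

Test and acceptance workloads use 10⁴ random reads for the clipper
oracle, 10³ randomized instances for interval and hairpin brute-force
equivalence, 5·10⁴-read libraries for assignment fidelity and 2·10⁴-read
libraries per point of the RT-drop-off grid — sizes at which binomial
sampling error is far below the asserted margins while the whole suite
runs in seconds. All randomness flows from explicit seeds; simulator
outputs and bedGraph/manifest files are byte-stable across reruns.
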