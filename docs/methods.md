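# Methods

`ngscompose` preprocesses Illumina-style FASTQ data from multiplexed,
enzyme-fragmented libraries whose construct layout is known in advance:
a fixed-length buffer region, an inline variable-length sample barcode, and
a restriction-site (or A-tail) motif precede the genomic insert on both
mates.  Because the expected sequence at the 5' end of every read is known,
base-calling error can be detected *empirically*, independently of the
instrument's Phred scores.  This note records the models, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Read and quality model

Reads are 4-line FASTQ records, single- or paired-end, plain or gzipped.
Qualities are Phred+33 with the standard 41 bins (Q 0–40); characters
outside that range are a hard error rather than being clamped, since they
indicate a mis-detected encoding.  Phred+64 is not auto-detected.  Wrapped
(multi-line) FASTQ and interleaved files are unsupported.

Every file-level stage reports `reads_in`, `reads_out` and
`reads_discarded`, and writes all rejected populations to files, so the
conservation identity `in == out + discarded` is checkable at every step
and failing reads remain available for comparison.

## QC summaries (crinoid)

Per-position composition is tallied by walking reads `k` bases at a time
(default k = 6) and counting unique chunks in a dictionary, then expanding
to a 5 × n nucleotide matrix (A, C, G, T, N) and a 41 × n Q-score matrix,
n being the maximum observed read length.  The chunk walk is an efficiency
device only: the matrices are identical for every k, which is the defining
contract (property-tested).  The column sum at position p equals the number
of reads longer than p.  Ambiguity codes other than N are tallied under N
with a warning.

## Trimming (scallop)

Fixed trimming removes set base counts from either end (the 6 bp buffer
before demultiplexing is the canonical use).  Because conventions differ,
`-b` means "remove N bases from the 3' end" by default, with an absolute
cut-position variant exposed separately.

Quality end-trimming slides a window of size `w` base-by-base from the 3'
end towards the 5' end and cuts the read at the 3' edge of the first window
whose every base is at or above the threshold `e`; the qualifying window
itself is kept, preserving the highest-quality suffix boundary.  If no
window qualifies the read empties and is discarded; its mate drops into a
single-end lineage rather than being written as an empty record.  The
operation is idempotent.

## Demultiplexing (anemone)

Inline barcodes (7–10 bp in the designs emulated here) are matched against
the read prefix of each barcode's own length.  Assignment is staged:
an exact pass (Hamming distance 0) first, then optional passes at
m = 1, 2, …, each consuming only reads left unknown.  At every pass a read
whose prefix is within the current tolerance of **more than one** barcode is
kept as unknown — including the nesting case where a shorter barcode is an
exact prefix of a longer one.  Assignment is therefore independent of
barcode file order, and a read is never assigned by preference; this is the
property that makes the downstream empirical error estimates trustworthy.

A barcode set with minimum pairwise Levenshtein distance d cannot uniquely
identify reads once 2m ≥ d, so such tolerances are refused unless
explicitly overridden (the override exists because error profiling
deliberately stretches the tolerance; see below).  Distances are computed
with edlib.

Dual-index schemes reconcile the forward (R1) and reverse (R2) assignments
through the sample matrix; one output file exists per sample cell for each
category — paired R1/R2 plus single-end (`se.`) R1/R2 — so a full 96 × 96
scheme fans out to 9216 files per category.  A pair with exactly one
matched mate cannot be resolved to a dual-index cell and goes to the
unknown files untrimmed, unless the matched direction alone is decisive.
Matched barcodes are trimmed from the 5' end; unknown reads keep their
original sequence.

## Motif filtering (rotifer)

Reads are required to begin — position 0, exact match — with one of the
expected motifs (OR-ed over the list): TGCAT/CATG for the NsiI/NlaIII
double digest, TCC/TCT-style lists for A-tailed blunt-end designs.  No
mismatch tolerance is applied because an erroneous motif *is* the error
signal the filter exists to detect.  Reads are routed, never modified:
both-pass pairs stay paired, a lone passing mate goes to an `se.` file, and
failing reads go to fail files.

## Q-threshold filtering (krill)

A read passes when at least `p` percent of its bases have Q ≥ `q`
(Q30/P90 is the conventional protocol).  The failing allowance
`(100 − p)/100 · length` is kept as an exact rational — the comparison is
`100 · failing ≤ (100 − p) · length` — so a count exactly at the allowance
passes and fractional allowances are not floored.  Qualities are scanned
3'→5' with early rejection; the early exit provably matches full counting.

## Adapter read-through removal (porifera)

Each expected adapter — preferably the composite of reverse-complemented
barcode + buffer + outer adapter, which places sample-specific sequence
upstream of the 3' quality drop — is split into k-mers (default k = 8)
stored with their offset from the adapter start.  Scanning proceeds in
rounds: round 1 examines offsets {0, k, 2k, …}, round 2 {1, k+1, …}, for
`r` rounds (default 3).  Each occurrence of an indexed k-mer at read
position p with offset o votes for start index p − o; votes are counted as
distinct supporting offsets, so repeated k-mers cannot double-vote.
Candidates are evaluated at the end of each round; the threshold is m
votes (default 2) and ties resolve to the 5'-most start (maximal removal
being the conservative choice for contamination).

Two additional acceptance rules make the voting robust in practice:

* **Minimum overlap** (default 12 bases, following the benchmark convention
  for unbiased comparisons): a hit whose start leaves fewer adapter bases
  inside the read is not trusted on votes alone and requires confirmation
  by the optional Smith-Waterman mode.
* **Template verification**: any nine consecutive matching bases vote at
  two adjacent offsets and can reach m = 2 by chance, so every voted
  candidate is Hamming-checked against its template across the overlap and
  accepted only within max(1, 10 % of overlap) mismatches.  At this setting
  the expected chance-trim rate is on the order of 2 × 10⁻⁶ per read, and
  zero-mutation validation libraries show no false-positive trims; the
  trade-off is that a short overlap carrying two or more substitutions is
  skipped rather than trimmed.

A start index before the read start trims the whole read; reads shorter
than `min_len` (default 50) after trimming are discarded, their mates
surviving as single-end.  The optional Smith-Waterman mode (match +1,
mismatch −1, gap −2 — chosen as the simplest standard scoring) qualifies a
hit when the aligned block spans at least `t` adapter bases, and covers
terminal overlaps too short for k-mer voting.  In pipeline mode the search
space is restricted to each sample's own barcode-bearing adapters, which is
both faster and at least as specific; position-equivalence with the
standalone search is tested on mutation-free data.

## Evaluation metrics

**Read compression.**  Reduced-representation libraries sequence each locus
as many identical fragments, so collapsing identical reads (after
end-trimming to uniform length — mixed lengths are refused without an
override) shrinks the multiset substantially.  The compression rate is
`(1 − unique/total) · 100`; the raw unique/total ratio is also reported.
Base-call errors mint novel singleton reads and lower the rate, so the rate
doubles as a reference-free error proxy.  Δ-compression of a filtered
subset is normalized against random subsamples of the raw file of the same
size (without replacement, seeded, 10 replicates by default, mean and SD
reported) to remove the pure sample-size effect.  A filter that
preferentially removes error-bearing reads gives Δ > 0 on its pass set and
Δ < 0 on its fail set.  Reads containing N are collapsed as distinct
literal strings.  A helper strips the matching motif-length prefix so the
comparison can be repeated on the non-motif portion of reads.

**Barcode error profiling.**  Barcodes are the only read bases whose true
sequence is known, so demultiplexing at staged mismatch levels and
comparing assigned reads base-by-base to their barcode yields an empirical
per-position error probability: at level M, the mismatching bases at
position j divided by all reads assigned at level M and fewer.  The
companion tally of instrument-reported Q scores at the same positions
allows the reported and empirical Phred values (Q = −10·log₁₀ p, with an
infinity sentinel at p = 0) to be compared directly.  Levels beyond the
identifiability bound of the barcode set require the explicit override, and
estimates at a level near the barcode length are mildly truncated (reads
with more errors than the level cannot be assigned); at the simulated
scales used in validation this bias is well inside 3 binomial SD.

## Simulator

The simulator generates the validation conditions rather than mimicking any
particular dataset:

* **Genome**: i.i.d. random sequence at a chosen GC fraction (default 0.4,
  typical of plant genomes) and length, seeded; or any FASTA.
* **Digest**: in-silico double digest with NsiI (ATGCA^T) and NlaIII
  (CATG^).  Cut offsets encode the 3' overhangs explicitly: both fragments
  flanking a site retain the overhang bases, so retained
  (mixed-end) fragments begin with TGCAT and end with CATG after
  orientation.  Fragment boundaries are validated against an independent
  regex-scan oracle.  A blunt-digest preset (AluI/HaeIII with A-tailing,
  giving a T start motif) shares all machinery.
* **Length law**: fragments are drawn with replacement with weights from a
  Normal(400, 100) density truncated to [30, 800] — the distribution used
  for benchmark simulation — so each locus is sequenced many times over.
* **Construct**: 6 bp buffer + barcode + insert + reverse-complemented
  opposite barcode, buffer and outer adapter; R1/R2 are the first
  `read_length` (default 150) bases of each strand.  Read-through occurs
  exactly when the insert ends before the read does, and the per-read truth
  table records sample identity, genome coordinates, both adapter start
  indices, and the unmutated sequences.
* **Qualities**: per-position Gaussian around a plateau of Q38 with a 5'
  ramp from Q33 and a 3' decay to Q31 (σ = 1.5), emulating the
  characteristic end-of-read decline without modelling any platform's
  binning.
* **Mutation**: independent per-base substitutions, uniform over the three
  alternatives, at a scalar or per-position rate (so error can be
  concentrated in chosen regions, e.g. to couple motif errors with
  elevated whole-read error); indels are not modelled, matching the
  Hamming-based matching downstream.  Mutation is a separate seeded step so
  one library can be emitted at several error rates.

Barcode sets are grown by seeded rejection sampling at lengths 7–10 under a
minimum pairwise Levenshtein distance of 3, with exact prefix nesting
rejected outright (a nested pair keeps edit distance 3 yet collides during
prefix matching).

Everything is deterministic given the configuration and seed.

## What the synthetic validation shows — and does not

Passing the simulation round trip demonstrates that the implementation is
faithful to its contracts: error-free conforming reads survive every stage,
sample assignment and adapter trim positions match the generated truth
exactly, and injected error rates are recovered within binomial
uncertainty.  It does not demonstrate performance on real data: the
simulator has no PCR duplicates or chimeras, no indels, no
platform-specific Q binning or correlated error structure, and an i.i.d.
genome with no repeats.  Real-library quantities (Δ-compression values,
platform error profiles) depend on those properties and on the actual
sequencing runs.

## Problem sizes used in validation

The standard validation suite uses a 2 Mb synthetic genome, libraries of
1 500–50 000 pairs, a 12 × 8 dual scheme for the pipeline round trip, the
full 96 × 96 scheme for the demultiplexing fan-out, 10 000 reads for the
adapter-scan oracle comparison, and 20 000 reads per rate for error-rate
recovery — sizes at which the binomial tolerances above are discriminating.

## Pipeline orchestration

The canonical order is buffer trim → demultiplex → motif filter → quality
end-trim → Q-threshold filter → adapter trim; the only configurable
reordering is the end-trim/threshold swap, since stage order materially
affects results and other orders are better run standalone.  Configuration
is a declarative key=value file rather than executable code, for
testability; walkthrough mode confirms or updates each stage's parameters
interactively or from a scripted answers file, and a non-interactive run
without answers aborts.  Single-end reads inherited from upstream stages
bypass the dual-index demultiplexer (a lone mate cannot be resolved to a
sample cell) and are carried through the remaining filters in a single-end
lineage.  Randomness (only the evaluation subsampling) derives from one
config-level seed; reruns are deterministic.
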