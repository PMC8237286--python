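# Methods

## Model and data structures

The classifier decides, from a prefix of a base-called nanopore read,
whether the read approximately matches a target reference collection.  It
avoids alignment entirely: the decision statistic is the distribution of
match lengths of the read against the indexed text.

**Texts.**  The positive text concatenates every reference record and its
reverse complement; the null text is the per-document character reversal
of the positive text (both strands reversed), so null and positive have
identical length, nucleotide composition and homopolymer structure.  A
single separator symbol `$` sits between consecutive documents and at the
end; `$` sorts before every base and never matches a read base, so no
match crosses a document boundary.  Ties among separator-led suffixes are
broken by suffix position (the standard distinct-terminator emulation),
which makes the suffix array, and hence the BWT, well defined with one
separator symbol.  LF steps from separator rows use a small explicit
table, because their F-column order follows separator position rather than
BWT row order; query walks never traverse these rows, but the table keeps
LF a true permutation.

**Index.**  The index stores the run-length encoded BWT (r runs), a
per-character occurrence table answering rank/LF in `O(log r)` per step,
and thresholds: for every pair of consecutive same-character runs, a row
attaining the minimum of the LCP array in the half-open interval
`(end_of_first, start_of_second]`.  When several rows attain the minimum,
the smallest row is chosen — any minimum is correct for the jump rule;
fixing one makes outputs deterministic.  In MS mode the index additionally
stores SA values at the first and last row of every run and the text
itself for second-pass verification; in PML mode neither is kept.

**Construction** is direct and in-memory: a numpy prefix-doubling suffix
array (`O(n log^2 n)`), Kasai's LCP algorithm, and a linear scan for runs
and thresholds.  This comfortably handles desk-scale references (hundreds
of kilobases to a few megabases); scaling to multi-gigabase collections
would require external construction techniques that are out of scope here.

## Matching statistics and pseudo-matching lengths

`matching_statistics` implements the exact two-pass algorithm.  Pass one
walks the pattern right to left maintaining a (row, position) pair with
`pos = SA[row]`: on BWT agreement one LF step extends the match and the
position decrements; on disagreement the engine jumps to the nearest run
of the required character above or below, the side chosen by comparing the
current row with the stored threshold, and re-seeds the position from the
boundary SA sample.  Pass two converts positions to lengths right to left:
when consecutive positions chain (`pos_i == pos_{i+1} − 1`) the length is
`MS[i+1] + 1`; otherwise it is obtained by direct character comparison
against the retained text.  A character absent from the index yields
`MS[i] = 0` (sentinel position) and the walk restarts from the terminator
row; restarting keeps the `pos = SA[row]` invariant, which the second pass
relies on, rather than leaving the pair inconsistent.

`pseudo_matching_lengths` is the one-pass streaming surrogate: a length
counter incremented when the BWT character at the current row equals the
next base, reset to zero on a jump.  PMLs ignore the possibility that a
jump continues a half-maximal match, so they are never larger than the
true MS (a property the suite checks on thousands of random pairs), but
long true matches still produce long PMLs.  The cursor (`StreamState`) is
an explicit value, so computation suspends and resumes between chunks with
bit-identical results for any chunking.  A fresh stream starts at row 0
(the terminator row): deterministic, and the first base almost always
jumps anyway.

## Streaming orientation

The MS/PML recurrences run right-to-left over a pattern, but the sequencer
delivers bases left-to-right.  The default mode consumes bases in arrival
order, treating each as one backward-extension step, which equals
computing statistics of the *reversed* read.  A reversed target-read
substring is found in the reversal of the indexed documents; consequently,
for a target read the long matches surface against the null index (whose
reversal is the positive text) and the positive index supplies the
random-baseline lengths — the two profiles swap roles relative to the
batch-oriented convention.  The windowed KS statistic is symmetric in its
two samples, so the decision rule is unaffected, and for non-target reads
both profiles are random either way.  This choice honours the
suspend/resume contract exactly (no base is ever revisited).  The
`--batch-independent` option instead scores each 180-base batch on its
own, right-to-left within the batch — the orientation in which the
positive profile carries the signal — at the cost of discarding
cross-batch context.  Diagnostic density reports (`density_report`) should
be read with the default-mode role swap in mind.

## Decision rule

Per 90-bp non-overlapping window (trailing partial windows discarded so
the threshold calibration retains its meaning), both samples are
transformed by subtracting the mean of the *window's* null values and
flooring at 1.  The windowed scope keeps each comparison self-contained
and streaming-compatible; the transform collapses random-length matches
onto the value 1, which concentrates both ECDFs when the read is random
(small KS) and separates them when positive matches are genuinely long.
Applying the transform to both samples preserves the symmetry of the KS
comparison.  The two-sided two-sample KS statistic (scipy) is compared
with 0.10 for PML profiles and 0.25 for MS profiles.  The read-level call
requires a strict majority of windows above threshold; with an even window
count an exact tie is *not* a majority (conservative: fewer false
ejections).  By default each batch's decision uses all complete windows
accumulated since the read began — strictly more information per decision
than scoring the newest batch alone.

## Read Until harness

`run_read` delivers a read in 180-base chunks, at most 4 (720 bases ≈
1.6 s at ~450 bases/s; the conversion is a fixed base cap, no wall-clock
simulation).  After each batch the classifier runs; on a match the read is
ejected at that batch and delivery ceases — profiles are never extended
past the ejection point.  Reads shorter than one window defer with an
insufficient-data flag.  The positive index holds depletion targets; the
`enrich` flag inverts the action (reads never called a match are ejected
at their final batch) without touching the classifier.  Metrics follow the
depletion convention: TP = ejected target, FP = ejected non-target, FN =
kept target, TN = kept non-target; precision and recall fall back to 1.0
on empty denominators.

## Synthetic data

The generator emulates the study conditions at desk scale.  References
are uniform random DNA; `make_pangenome` derives near-identical strains
from one ancestor by i.i.d. substitutions (default divergence 0.1%),
reproducing the repetitiveness that keeps r almost flat as strains are
added.  Target reads are 720-bp reference substrings, either strand,
corrupted at a configurable mean accuracy (85–98%, the usual nanopore
base-calling range) with the error budget split 55% substitutions / 25%
insertions / 20% deletions — a fixed approximation of nanopore error
composition, configurable because no single split is canonical.
Non-target reads are uniform random DNA (matching the null-index
rationale), or substrings of a second, unrelated simulated genome when a
biological decoy is wanted.  What this does **not** emulate: signal-level
artefacts, homopolymer-length-dependent error rates, chimeras, adapter
sequence, quality-score structure, or real community composition — so
passing tests demonstrate correctness of the method and its
implementation, not field performance on real flow cells.

## Problem sizes and numerical choices

The test suite and the acceptance script run on a 100-kb single-record
reference (positive text ≈ 200 kb), 500–1000 reads per condition, and an
80-kb synthetic pan-genome — sizes chosen so the full pipeline, including
index construction from scratch, completes in well under a minute while
leaving every code path at realistic operating conditions (the 90-bp
window, 180-base chunk and 0.10/0.25 thresholds are the published
operating point and are left untouched).  At this index size the exact-MS
mode is noticeably less sensitive than the PML mode at 85–90% read
accuracy: both null and positive MS are long relative to PMLs, and the
0.25 threshold — calibrated on genome-scale indexes — is harder to clear;
the same ordering (PML ≥ MS at low accuracy) appears in the original
study's genome-scale tables.  Serialization uses a single binary container
(magic `PSIX`, version, mode flag, tagged length-prefixed sections);
truncation, wrong magic or a missing section raise a format error, and a
PML-mode file refuses MS queries.

## Known limitations

* In-memory construction only; no prefix-free-parsing or grammar-based
  compression, so MS-mode indexes store the plain text.
* Operates on base space; no raw-signal handling or real Read Until API
  integration, and no base-calling.
* KS thresholds are taken as published, not re-calibrated per dataset;
  with conserved sequence shared between targets and non-targets the
  reversal-based null can be too permissive.
* No occurrence locating or alignment output — classification only.
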