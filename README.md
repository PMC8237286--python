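# porescreen

Streaming read classification for nanopore adaptive sampling ("Read
Until"), built on a run-length compressed BWT (r-index) with thresholds.

## The problem

Nanopore sequencers can eject the molecule currently in a pore by
reversing the voltage, so control software that recognises an unwanted
read from its first few hundred bases can reclaim the pore for something
more interesting (depleting host DNA, enriching a rare species, …).  Data
arrives in ~0.4 s chunks — roughly 180 bases at ~450 bases/s — so the
decision procedure must be incremental, fast, and memory-frugal enough to
index large, repetitive reference collections such as pan-genomes.

`porescreen` decides whether a read prefix has a good approximate match to
a set of target sequences *without aligning it*, using matching statistics
computed against two indexes:

* **positive index** — the targets, forward and reverse-complement;
* **null index** — the character-wise *reversal* (not the reverse
  complement) of the positive sequences: a composition- and length-matched
  stand-in for random sequence (nucleotide frequencies and homopolymers
  are preserved).

If the distribution of match lengths against the positive index separates
from the null distribution, the read matches a target.

## The statistics

For a pattern `P[1..m]` and text `T`, the matching statistic `MS[i]` is
the length of the longest prefix of `P[i..m]` occurring in `T`.  The
r-index computes MS in two passes over the run-length encoded BWT using
*thresholds* — one row per pair of consecutive same-letter BWT runs,
marking a minimum of the LCP array between them, which tells a mismatching
backward-search step whether to jump up or down.  The streaming mode drops
the second pass entirely and reports **pseudo-matching lengths** (PMLs): a
running length incremented whenever the BWT character agrees with the next
pattern character and reset to zero on a jump.  PMLs never exceed the true
MS, need neither SA samples nor the text (the index is just the RLBWT plus
thresholds, `O(r)` space), and suspend/resume cleanly between chunks.

Per non-overlapping 90-bp window the two profiles are compared after a
variance-sharpening transform (subtract the null-window mean, floor at 1)
with the two-sample Kolmogorov–Smirnov statistic `D = sup_x |F_pos(x) −
F_null(x)|`; a read is called a match iff a strict majority of its windows
exceeds the calibrated threshold (0.10 for PMLs, 0.25 for MS).

## Worked example

```sh
porescreen simulate --out-refs refs.fa --out-reads reads.fq --seed 42 \
    --accuracy 0.90 --n-reads 200 --read-len 720 --ref-len 50000 \
    --frac-nontarget 0.5
porescreen build --ref refs.fa --out idx
porescreen classify --index idx --reads reads.fq --out outcomes.tsv
porescreen evaluate --outcomes outcomes.tsv
```

which prints (logs to stderr, table to stdout):

```
[porescreen] positive index: n=100002 r=75206 -> idx.pos.idx
[porescreen] null index: n=100002 r=75213 -> idx.null.idx
[porescreen] 200 reads: F1=100.00% precision=100.00% recall=100.00% specificity=100.00%
metric  value
tp      100
fp      0
fn      0
tn      100
accuracy        1.0000
precision       1.0000
recall  1.0000
specificity     1.0000
f1      1.0000
```

All 100 reads simulated from the 50-kb reference at 90% accuracy were
ejected (every one after the first 180-base chunk: `eject_batch` 1 in
`outcomes.tsv`), and none of the 100 random decoy reads were touched.  A
true positive is an ejected target read; a false positive is an ejected
non-target read; a false negative is a target read still in the pore after
4 chunks (720 bases).

The library API mirrors the CLI: `build_positive_text` / `build_null_text`
→ `build_index` → `pseudo_matching_lengths` or `matching_statistics` →
`classify_read` / `run_read` / `evaluate`.

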