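# Methods

This note records the models, rules and numerical conventions the package
implements, the reasoning behind the genuinely open design choices, and
what the synthetic-data generator does and does not emulate.

## Reading and decoding

FASTQ parsing is strict 4-line: any structural defect (wrapped lines,
missing sentinels, sequence/quality length mismatch) is a hard error
naming the record, because a lenient parser would silently mis-frame every
subsequent record. Decoded qualities are capped at 60 (one warning);
compressed input is refused with an actionable message.

PHRED offset detection uses the disjointness of the two encodings' ASCII
ranges: any code < 59 proves offset 33; all codes ≥ 64 with at least one
> 74 indicate offset 64. Codes confined to [64, 74] are consistent with
both (very low qualities at +33 or mid qualities at +64); we default to 33
with a warning, the safer choice for modern data.

Learning subsamples are the first 1,000 records of each file. Head
sampling is deliberate: it is reproducible without a seed and matches the
single-pass use of the subsample; a random mode would buy representativeness
the learning heuristics do not need (they threshold coarse aggregates).

## Demultiplexing

Barcodes are compared to read prefixes by Hamming distance with asymmetric
IUPAC semantics: an ambiguity code in the *barcode* (including leading `N`
runs used for stagger) matches any compatible base at zero cost; an `N` in
the *read* is evidence of nothing and costs 1 against any concrete barcode
base. A read is assigned to the unique minimal-mismatch sample within the
budget; ties go to the unassigned pool rather than to an arbitrary winner,
trading a little yield for zero silent misassignment. For paired barcodes
both mates must match the same sample, each within the budget.

Collision checking answers: can one mismatch budget make two samples claim
the same read? Exactly: a pair collides iff some read prefix lies within
`max_mismatch` of both barcodes. Rather than enumerating 4^L prefixes we
run a positionwise dynamic programme tracking, for each achievable
mismatch total against barcode 1, the minimal total against barcode 2 —
exact for any length and ambiguity content, polynomial cost. The 4^L
enumeration survives as the independent oracle in the tests.

An off-start search window (`search_window`, default 0 = disabled) scans
barcode start offsets 0..k for protocols that place barcodes inside the
read; the window size is exposed because no principled universal bound
exists.

## Adaptor clipping and detection

Simple mode places each adaptor semi-globally against the read (the
adaptor may overhang the 3′ end), scoring +1 per match and −1 per
mismatch. A placement qualifies at score ≥ 12 with ≤ 2 mismatches in the
8-nt seed; the read is truncated at the best qualifying start. The score
floor means adaptor remnants shorter than ~12 nt are invisible to simple
mode — the same detection limit the classical tools have; after stitching,
such remnants surface as low-quality conflicts and are removed by the
floor trimmer instead.

Palindrome mode handles read-through on mate pairs. Overlapping read 1
against the reverse complement of read 2 in the "outie" geometry yields
the implied insert length L; if the alignment scores ≥ 30 and L is shorter
than the reads, each mate whose overhang (bases beyond L) matches one of
the set's adapters (≤ 25% mismatches over ≥ 6 compared bases, against the
set's sequences and the reverse complements of its ligated `Prefix`
adapters) is truncated to L. The per-mate adaptor anchor matters twice
over: it is what the underlying chemistry predicts (the overhang *is* the
opposing adapter's reverse complement), and it is what lets closely
related adaptor families be distinguished — the TruSeq2 and TruSeq3
families share one read-through sequence entirely, so only the other
mate's overhang carries signal. Unverified mates fall back to simple mode.

Adaptor-set detection operationalises "smallest output" as fewest total
retained bases on the subsample after clipping with each candidate — a
deterministic, format-independent proxy for output file size. Ties break
to the lexicographically first name. If the winner removes less than
0.25% of all bases, the data are declared adaptor-free ("None"): genuine
contamination at the paper-relevant levels removes orders of magnitude
more, while spurious matches on clean data sit well below this floor.

The four built-in sets ship as FASTA files inside the package
(`autoshi/adaptors/`) and any user FASTA path can replace a set name.

## Stitching

All innie overlap lengths v in [min_overlap, min(max_overlap, |r1|, |r2|)]
are scored between read 1 and the reverse complement of read 2 (plus outie
placements when enabled — off by default). Placements with mismatch
density ≤ 0.25 qualify; the winner has minimal density, ties broken toward
the longer overlap, then toward innie. Density rather than raw mismatch
count keeps the acceptance rule scale-free across overlap lengths; the
explicit tie-break exists because tied placements do occur and the result
must be deterministic. The scan is exact and vectorised (per-base
indicator cross-correlation gives match counts at every lag at once); the
tests pin it to a brute-force all-offsets scorer.

Consensus: agreement keeps the shared base at max(q₁, q₂); disagreement
keeps the higher-quality base (ties to read 1) at quality
max(2, |q₁ − q₂|). The contract this must satisfy is that conflicted
regions — overlaid opposing adaptors after full-read-length stitching —
come out with very low scores so the floor trimmer removes them; |q₁ − q₂|
is a natural confidence for "which of two contradictory calls is right",
and the floor of 2 keeps the value in range and unmistakably low.

Merged-length statistics use the population SD (ddof = 0) of the observed
merged lengths; CV = σ/μ. With zero successful stitches the statistics
are flagged (NaN), not an error — "nothing stitches" is a legitimate
finding that downstream classification consumes.

## Floor trimming and filtering

From the 5′ end: while the next `window` bases (default 4) contain any
base below the head floor, drop the first base; then the same from the 3′
end with the tail floor; a remainder shorter than the window is tested as
one window. The output is always a contiguous substring with clean
terminal windows, and the operation is idempotent. Head trimming runs to
completion before tail trimming; the order is immaterial to the result but
fixed for reproducibility. Note the rule is sequential by definition: a
read like qualities [30, 5] with window 2 trims to empty (the first window
is never clean), even though the bare substring [30] would have clean
terminal windows — the trimmer never "skips over" a dirty window.

Filtering drops reads shorter than `min_length`, then reads whose mean
quality is strictly below `min_avg_q` (a read exactly at the threshold is
kept — consistent with an integer threshold learned as the floor of a
fractional mean).

## Learning mode

Order of operations: subsample → PHRED detection → pair detection →
(in-memory barcode stripping when `oligos.txt` is present) → adaptor
detection and clipping (paired mode iff pairs detected) → trial stitching
with generous bounds (min overlap 10, max 700) → classification → quality
learning on the fully processed subsample. Learning never writes to the
input directory.

Pair detection requires an even file count and an ordered token-pattern
list (`R1/R2`, `_1/_2`, `0.1/0.2`, …); the first pattern that perfectly
partitions the files into otherwise-identical name pairs wins, otherwise
the run is single-end.

Classification: stitch fraction < 0.25 → unstitchable (stitching is then
disabled); CV < 0.1 (strict) → amplicon; otherwise shotgun. For amplicons
the merged-length band is round(μ ± k·σ) with k = 2 by default (exposed as
`--bound_sd`; the band is deliberately configurable because reasonable
choices between ±0.5 and ±2 SD exist and the right width depends on how
aggressive contaminant removal should be). The band renders under the
conventional flag names `--min_overlap`/`--max_overlap` and is applied as
the final merged-length gate after trimming, so every emitted read
verifiably lies inside it.

Quality learning: `filter_qual` = ⌊mean base quality over all bases⌋;
`trim_qual` = ⌊(mean + terminus)/2⌋ clamped to ≤ `filter_qual`, where the
terminus quality averages the first and last 10 bases of each read. The
midpoint is a fixed convention for the documented "between the dataset
mean and the terminus mean" recommendation; flooring (not rounding) keeps
the integer thresholds conservative. The quality pass reuses the initial
subsample after clipping and stitching rather than re-drawing — the same
reads the earlier stages were judged on.

## Pipeline

Stage order: demultiplex → clip → stitch → trim → filter (length, mean
quality, amplicon band) → format conversion; every stage is switchable.
A merged pair consumes two input records and emits one; the accounting
("stitched_mate_merged", "unstitched", "length", "quality",
"length_band", "unassigned_barcode") always balances input = output +
dropped, and the run aborts if it does not. When stitching is off, paired
files pass through as synchronised pairs (a mate failing a filter drops
the whole pair). Threads parallelise across samples with results written
in sorted sample order, so multi-threaded output is byte-identical to
single-threaded. The combined FASTA uses `<sample>_<serial>` headers
(serials 0-based per sample, samples sorted, names sanitized to
alphanumerics and dots); a post-sanitization name collision is a hard
error rather than a silent merge of two samples.

## Synthetic data generator

`fixtures.generate_run` emulates exactly the features the learner keys on:

- **Insert lengths**: truncated normal (≥ 1). Amplicon condition:
  253 ± 4 nt on 2×300 bp reads — a 16S-V4-like target where every read
  runs through into the opposing adaptor; shotgun condition: 150 ± 21 nt
  on 2×100 bp reads, the regime where merged lengths are capped at
  100 + 100 − min_overlap.
- **Read-through**: whenever the insert is shorter than the read, the
  reverse complement of the opposite-end adapter (the set's `*_rc` entries,
  or derived from its `Prefix` adapters) is appended, then random filler.
  `spike_fraction` additionally forces that fraction of fragments short
  (uniform 40–85% of the read length) to create read-through in libraries
  whose typical insert exceeds the read length.
- **Contaminants**: a configurable fraction of fragments drawn uniformly
  long (default 350–450 nt), mimicking the PhiX-like long tail that the
  amplicon length band is meant to remove.
- **Barcodes**: per-fragment sample assignment, concrete instantiation of
  IUPAC positions, optional per-base barcode error rate.
- **Qualities**: head/body/tail segment means (defaults 33/36/30, SD 3,
  clamped to [2, 40]) — the U-shaped-in-reverse profile of declining 3′
  quality.
- **Errors**: per-base substitutions with probability 10^(−q/10) from the
  assigned quality, so the quality string and the error process agree.

Everything is driven by one seeded generator; the same seed reproduces the
files byte for byte. The truth table stores, per fragment: sample, insert
length, appended adaptor lengths, the error-free reads and every injected
error, so each emitted read can be reconstructed exactly.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: indels and platform-specific error motifs,
quality–sequence context correlation, chimeras, optical duplicates, GC
bias, and real taxonomic composition. Recovery rates measured here show
the inference logic is correct under its stated model, not that the
thresholds are optimal for any particular instrument.

## Problem sizes and numerical conventions

Learning-mode studies use 1,000 fragments (~2,000 reads) per run and 20
seeded runs per scenario; oracle-equivalence suites use 1,000 random
pairs/reads and brute force on reads ≤ 30 nt. Bounds are rounded with
floor(x + 0.5) (no banker's rounding); quality thresholds floor; all
comparisons against thresholds are as stated above (filters strict-below,
floors pass at ≥, CV strict-below 0.1). Degenerate inputs are defined,
not errors: empty reads trim/filter cleanly, zero stitches flag NaN
statistics, and an empty adaptor set is the identity clip.
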