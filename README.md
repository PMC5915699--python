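# autoshi

Self-learning quality control for short-read DNA sequencing data.

Raw FASTQ output from a sequencing run cannot be analysed directly: reads
carry platform adaptors, sample barcodes, and low-confidence bases, and the
right clean-up parameters depend on details of the library preparation
(adaptor chemistry, insert size, paired-endedness, amplicon vs shotgun
design) that are often unknown — especially for public data or data from
collaborators. `autoshi` is a complete, self-contained QC pipeline for
microbiome and general metagenomics workflows that *infers* those
parameters from a subsample of the data itself, reports them as an
explicit, editable command line, and then runs the full pipeline:

1. **Demultiplexing** — error-correcting barcode assignment from a
   MOTHUR-format `oligos.txt` (IUPAC-ambiguous and staggered barcodes,
   user-set mismatch budget, collision diagnostics).
2. **Adaptor clipping** — built-in TruSeq2 / TruSeq3 / TruSeq3-2 / Nextera
   sets (user-extensible FASTA), with per-read 3′ clipping and
   palindrome-mode read-through removal for mate pairs.
3. **Stitching** — merging each pair with the reverse complement of its
   mate over the best overlap; in the overlap, agreeing bases keep quality
   max(q₁, q₂), disagreeing positions keep the higher-quality base at the
   deliberately low quality max(2, |q₁ − q₂|), so conflicted regions are
   visible to the trimmer.
4. **Quality-floor trimming** — bases are shaved from each end until no
   base in the terminal window falls below the floor (not a window *mean*:
   a single bad base keeps trimming going), then length and mean-quality
   filters are applied.
5. **Output** — per-sample FASTQ, or one pooled FASTA with
   `<sample>_<serial>` headers ready for OTU picking.

## What learning mode infers

From up to 1,000 reads per file, `autoshi learn` determines:

- the PHRED encoding offset (33 or 64);
- paired-endedness, from file-name patterns (`R1/R2`, `_1/_2`, `0.1/0.2`, …);
- the contaminating adaptor set, as the candidate whose clipping leaves the
  fewest retained bases on the subsample ("None" if the best gain is
  negligible);
- whether pairs stitch reliably (fraction ≥ 0.25 by default);
- whether the library is amplicon-like: the coefficient of variation
  CV = σ/μ of merged contig lengths is below 0.1 for the near-uniform
  fragment lengths of marker-gene amplicons, and above it for shotgun
  libraries;
- for amplicons, a merged-length band μ ± 2σ used as a final length gate
  (removes long contaminants such as PhiX control sequences);
- quality thresholds: the mean base quality ⌊q̄⌋ as the per-read mean
  filter, and the midpoint of q̄ and the mean "terminus" quality (first and
  last 10 bases) as the end-trimming floor.

## Worked example

Generate a synthetic 16S-like run (1,000 fragments, 2×300 bp reads over
253 ± 4 nt inserts — short enough that every read runs through into the
opposing Nextera adaptor — plus 1% long PhiX-like contaminants), then learn
and run:

```python
from autoshi import FixtureSpec, generate_run
spec = FixtureSpec(seed=42, n_fragments=1000, read_len=300,
                   insert_mean=253, insert_sd=4, adaptor="Nextera",
                   contaminant_fraction=0.01, name="pmp_like")
generate_run(spec, "demo/reads")
```

```text
$ autoshi learn demo/reads --out demo/learned.yaml
--adaptor Nextera --flash True --allow_outies False --filter_qual 37 --trim_qual 36 --min_overlap 218 --max_overlap 292
# stitch fraction 1.000, merged-length CV 0.073 -> amplicon

$ autoshi run demo/reads --from-learned demo/learned.yaml -o demo/out
parameters: --adaptor Nextera --flash True --allow_outies False --filter_qual 37 --trim_qual 36
records: 2000 in, 962 out
dropped (length_band): 24
dropped (quality): 14
dropped (stitched_mate_merged): 1000
```

Reading the output: the learner recovered the spiked Nextera adaptors,
found that every pair stitches, and classified the run as an amplicon
(CV 0.073 < 0.1), so it set a merged-length band of 218–292 nt bracketing
the true 253 nt insert. The pipeline then merged all 1,000 pairs (each
merge consumes one of the two mate records — the 1,000
`stitched_mate_merged` entries), discarded 24 records outside the length
band (the long contaminants and heavily trimmed reads) and 14 for mean
quality below 37, leaving 962 clean contigs:

```text
$ head -2 demo/out/combined_seqs.fna
>pmp.like_0
GATCGCATTGCTGCCAAGTATTCGATGCATCTGTTACCCAGAGGTGCTCC...
```

Every surviving contig lies inside the learned band and has mean quality
≥ 37; record accounting always balances (input = output + dropped, by
reason).

## Limitations

- FASTQ records must not be line-wrapped; compressed input is rejected
  (extract first, e.g. `gunzip *`).
- Interleaved paired files are processed as single-end; only split-file
  pairs are treated as pairs.
- Barcodes are never auto-detected: demultiplexing requires `oligos.txt`.
- Overlap alignment is ungapped (no indels in the overlap region).
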