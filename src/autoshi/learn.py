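"""Self-learning of QC parameters from a subsample of the data.

From up to 1,000 reads per file the learner infers: the PHRED offset,
paired-endedness (file-name pattern matching), the contaminating adaptor
set (fewest-retained-bases rule), whether pairs stitch reliably (>= 25% by
default), whether the library is amplicon-like (coefficient of variation of
stitched lengths < 0.1), a merged-length band for amplicon runs (mean +/- 2
SD by default), and quality thresholds for filtering and end trimming.  The
result renders as a ready-to-run flag string and round-trips through
:func:`LearnedParams.parse`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import adaptor_clip
from .adaptor_clip import AdaptorSet, ClipParams, detect_adaptor_set
from .demultiplex import DemuxParams, _match_pair
from .fastq_io import (
    Read,
    detect_phred_offset_file,
    parse_oligos,
    subsample,
)
from .stitcher import OverlapStats, StitchParams, stitch_pairs

#: File-name token pairs tried, in order, to recognise mate files.
DEFAULT_PAIR_PATTERNS: Tuple[Tuple[str, str], ...] = (
    ("R1", "R2"),
    ("_1", "_2"),
    ("0.1", "0.2"),
    (".1.", ".2."),
    ("-1.", "-2."),
)

AMPLICON = "amplicon"
SHOTGUN = "shotgun"
UNSTITCHABLE = "unstitchable"


@dataclass(frozen=True)
class LearnConfig:
    subsample_n: int = 1000
    stitch_fraction_min: float = 0.25
    cv_amplicon_max: float = 0.1
    bound_multiplier: float = 2.0
    terminus_len: int = 10
    pair_patterns: Tuple[Tuple[str, str], ...] = DEFAULT_PAIR_PATTERNS
    #: Generous stitching defaults used during the learning pass.
    learn_min_overlap: int = 10
    learn_max_overlap: int = 700

    def __post_init__(self):
        if self.subsample_n < 1 or self.terminus_len < 1:
            raise ValueError("subsample_n and terminus_len must be >= 1")
        if not self.pair_patterns:
            raise ValueError("pair pattern list must be nonempty")


@dataclass(frozen=True)
class LearnedParams:
    """A complete inferred QC parameterization, renderable as a flag string."""

    single_end: bool
    adaptor: str
    do_stitch: bool
    filter_qual: int
    trim_qual: int
    allow_outies: bool = False
    min_overlap_bound: Optional[int] = None
    max_overlap_bound: Optional[int] = None
    amplicon_mode: bool = False
    phred: int = 33

    def __post_init__(self):
        if self.amplicon_mode:
            if self.min_overlap_bound is None or self.max_overlap_bound is None:
                raise ValueError("amplicon mode requires overlap bounds")
            if self.min_overlap_bound > self.max_overlap_bound:
                raise ValueError("min_overlap_bound > max_overlap_bound")
        elif self.min_overlap_bound is not None or self.max_overlap_bound is not None:
            raise ValueError("overlap bounds are set only in amplicon mode")

    def render(self) -> str:
        parts: List[str] = []
        if self.single_end:
            parts.append("-SE")
        parts += [
            "--adaptor", self.adaptor,
            "--flash", str(self.do_stitch),
            "--allow_outies", str(self.allow_outies),
            "--filter_qual", str(self.filter_qual),
            "--trim_qual", str(self.trim_qual),
        ]
        if self.amplicon_mode:
            parts += [
                "--min_overlap", str(self.min_overlap_bound),
                "--max_overlap", str(self.max_overlap_bound),
            ]
        return " ".join(parts)

    @classmethod
    def parse(cls, rendered: str, phred: int = 33) -> "LearnedParams":
        tokens = rendered.split()
        single_end = "-SE" in tokens
        vals: Dict[str, str] = {}
        i = 0
        while i < len(tokens):
            tok = tokens[i]
            if tok.startswith("--"):
                vals[tok[2:]] = tokens[i + 1]
                i += 2
            else:
                i += 1
        lo = vals.get("min_overlap")
        hi = vals.get("max_overlap")
        return cls(
            single_end=single_end,
            adaptor=vals["adaptor"],
            do_stitch=vals["flash"] == "True",
            allow_outies=vals.get("allow_outies", "False") == "True",
            filter_qual=int(vals["filter_qual"]),
            trim_qual=int(vals["trim_qual"]),
            min_overlap_bound=int(lo) if lo is not None else None,
            max_overlap_bound=int(hi) if hi is not None else None,
            amplicon_mode=lo is not None,
            phred=phred,
        )


def _replace_last(s: str, old: str, new: str) -> str:
    return s[::-1].replace(old[::-1], new[::-1], 1)[::-1]


def detect_pairs(filenames: Sequence[str],
                 patterns: Sequence[Tuple[str, str]] = DEFAULT_PAIR_PATTERNS
                 ) -> Optional[Dict[str, Tuple[str, str]]]:
    """Partition file names into mate pairs, or None for single-end.

    Requires an even file count and one pattern whose token substitution
    (rightmost occurrence) maps every "first mate" name onto a distinct
    existing "second mate" name, covering all files.  The first pattern in
    the ordered list that achieves a perfect partition wins.
    """
    if not filenames:
        raise ValueError("no file names given")
    files = sorted(filenames)
    if len(files) % 2 != 0:
        return None
    for a, b in patterns:
        firsts = [f for f in files if a in f]
        if len(firsts) * 2 != len(files):
            continue
        remaining = set(files) - set(firsts)
        pairing: Dict[str, Tuple[str, str]] = {}
        ok = True
        for f in firsts:
            partner = _replace_last(f, a, b)
            if partner in remaining:
                remaining.discard(partner)
                base = Path(_replace_last(f, a, "")).stem.strip("._-")
                pairing[base or f] = (f, partner)
            else:
                ok = False
                break
        if ok and not remaining:
            return pairing
    return None


def classify_library(stats: OverlapStats, cfg: LearnConfig = LearnConfig()) -> str:
    """amplicon / shotgun / unstitchable from the stitching statistics.

    Below the stitch-fraction threshold the pairs are unstitchable; a CV of
    merged lengths strictly below the amplicon threshold signals the length
    uniformity of amplicon libraries; anything else is shotgun-like.
    """
    if stats.n_pairs == 0 or stats.stitch_fraction < cfg.stitch_fraction_min:
        return UNSTITCHABLE
    if stats.cv < cfg.cv_amplicon_max:
        return AMPLICON
    return SHOTGUN


def compute_bounds(stats: OverlapStats, cfg: LearnConfig = LearnConfig(),
                   min_overlap_floor: Optional[int] = None) -> Tuple[int, int]:
    """Merged-length band mean +/- k*SD for amplicon runs.

    The lower bound is floored at the stitcher's minimum overlap so the
    band can never demand an impossible merge.
    """
    if stats.n_stitched < 2:
        raise ValueError("need at least two stitched pairs to set bounds")
    k = cfg.bound_multiplier
    lo = math.floor(stats.mean - k * stats.sd + 0.5)
    hi = math.floor(stats.mean + k * stats.sd + 0.5)
    floor = cfg.learn_min_overlap if min_overlap_floor is None else min_overlap_floor
    return max(lo, floor), hi


def learn_quality(reads: Sequence[Read], cfg: LearnConfig = LearnConfig()
                  ) -> Tuple[int, int]:
    """(filter_qual, trim_qual) from the processed subsample.

    filter_qual is the floor of the mean base quality over all bases;
    trim_qual is the floor of the midpoint between that mean and the mean
    "terminus" quality (first and last ``terminus_len`` bases of each
    read), clamped to not exceed filter_qual.
    """
    if not reads:
        raise ValueError("cannot learn qualities from an empty read set")
    total, n = 0, 0
    t_total, t_n = 0, 0
    k = cfg.terminus_len
    for r in reads:
        if not r.qual:
            continue
        total += sum(r.qual)
        n += len(r.qual)
        term = r.qual[:k] + r.qual[max(len(r.qual) - k, 0):]
        t_total += sum(term)
        t_n += len(term)
    if n == 0:
        raise ValueError("cannot learn qualities: all reads are empty")
    mean_q = total / n
    terminus_q = t_total / t_n
    filter_qual = math.floor(mean_q)
    trim_qual = min(math.floor((mean_q + terminus_q) / 2), filter_qual)
    return filter_qual, trim_qual


def _strip_barcodes(pairs_or_reads, specs, paired: bool):
    """Barcode-strip a subsample in memory (drop unassignable records)."""
    params = DemuxParams(max_mismatch=1)
    out = []
    for item in pairs_or_reads:
        if paired:
            r1, r2 = item
            sample, o1, o2 = _match_pair(r1, r2, specs, params)
            if sample is not None:
                out.append((o1, o2))
        else:
            sample, o1, _ = _match_pair(item, None, specs, params)
            if sample is not None:
                out.append(o1)
    return out


def learn_all(input_dir, cfg: LearnConfig = LearnConfig()
              ) -> Tuple[LearnedParams, Dict]:
    """Run the full learning pass over a directory of FASTQ files.

    Subsamples each file, then: PHRED detection -> pair detection ->
    adaptor detection/clipping -> trial stitching -> library classification
    (+ merged-length bounds for amplicons) -> quality learning on the fully
    processed subsample.  Input files are never modified.  Returns the
    learned parameters plus a diagnostics dict (pairing, stitch statistics,
    classification, subsample sizes).
    """
    input_dir = Path(input_dir)
    fastqs = sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in {".fastq", ".fq"}
    )
    if not fastqs:
        raise FileNotFoundError(f"no FASTQ files in {input_dir}")

    offset = detect_phred_offset_file(fastqs[0], cfg.subsample_n)
    sub = {p.name: subsample(p, cfg.subsample_n, offset=offset) for p in fastqs}

    pairing = detect_pairs([p.name for p in fastqs], cfg.pair_patterns)
    single_end = pairing is None

    if single_end:
        items = [r for p in fastqs for r in sub[p.name]]
    else:
        items = []
        for base in sorted(pairing):
            f1, f2 = pairing[base]
            if len(sub[f1]) != len(sub[f2]):
                raise ValueError(f"mate-count mismatch between {f1} and {f2}")
            items.extend(zip(sub[f1], sub[f2]))

    oligos = input_dir / "oligos.txt"
    if oligos.exists():
        specs = parse_oligos(oligos)
        items = _strip_barcodes(items, specs, not single_end)
        if not items:
            raise ValueError("no subsampled reads matched the oligos barcodes")

    clip_params = ClipParams()
    adaptor_name = detect_adaptor_set(items, paired=not single_end,
                                      params=clip_params)
    aset = AdaptorSet.load(adaptor_name)

    if single_end:
        clipped = [adaptor_clip.clip_read(r, aset, clip_params) for r in items]
        do_stitch = False
        amplicon = False
        stats = None
        classification = None
        bounds = (None, None)
        q_reads = [r for r in clipped if len(r)]
    else:
        clipped_pairs = [
            adaptor_clip.clip_pair_palindrome(r1, r2, aset, clip_params)
            for r1, r2 in items
        ]
        clipped_pairs = [(a, b) for a, b in clipped_pairs if len(a) and len(b)]
        sparams = StitchParams(cfg.learn_min_overlap, cfg.learn_max_overlap)
        results = stitch_pairs(clipped_pairs, sparams)
        lengths = [len(r.merged) for r in results if r is not None]
        stats = OverlapStats.from_lengths(lengths, len(clipped_pairs))
        classification = classify_library(stats, cfg)
        do_stitch = classification != UNSTITCHABLE
        amplicon = classification == AMPLICON
        bounds = (
            compute_bounds(stats, cfg) if amplicon else (None, None)
        )
        if do_stitch:
            q_reads = [r.merged for r in results if r is not None]
        else:
            q_reads = [r for pair in clipped_pairs for r in pair if len(r)]

    filter_qual, trim_qual = learn_quality(q_reads, cfg)

    params = LearnedParams(
        single_end=single_end,
        adaptor=adaptor_name,
        do_stitch=do_stitch,
        allow_outies=False,
        filter_qual=filter_qual,
        trim_qual=trim_qual,
        min_overlap_bound=bounds[0],
        max_overlap_bound=bounds[1],
        amplicon_mode=amplicon,
        phred=offset,
    )
    info = {
        "pairing": pairing,
        "offset": offset,
        "stats": stats,
        "classification": classification,
        "n_files": len(fastqs),
        "n_subsampled": sum(len(v) for v in sub.values()),
    }
    return params, info
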