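"""Paired-end overlap detection and merging with consensus qualities.

The merge scans every allowed overlap between read 1 and the reverse
complement of read 2, keeps placements whose mismatch density is within
bounds, and picks the lowest-density placement (ties toward the longer
overlap, then toward the convergent "innie" orientation).  In the overlap,
agreement keeps the shared base at the higher quality; disagreement keeps
the higher-quality base and marks the position with a deliberately low
consensus quality so that downstream floor trimming can remove conflicted
regions such as overlaid adaptors.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._align import encode, innie_matches, outie_matches
from .fastq_io import Read, reverse_complement

#: Consensus quality floor assigned at disagreeing overlap positions.
CONFLICT_QUAL_FLOOR = 2


@dataclass(frozen=True)
class StitchParams:
    min_overlap: int = 10
    max_overlap: int = 700
    max_mismatch_density: float = 0.25
    allow_outies: bool = False

    def __post_init__(self):
        if not (1 <= self.min_overlap <= self.max_overlap):
            raise ValueError("need 1 <= min_overlap <= max_overlap")
        if not (0.0 <= self.max_mismatch_density <= 1.0):
            raise ValueError("max_mismatch_density must be in [0, 1]")


@dataclass(frozen=True)
class StitchResult:
    merged: Read
    overlap_len: int
    mismatches: int
    orientation: str  # "innie" | "outie"


@dataclass
class OverlapStats:
    """Merged-length distribution of the successfully stitched pairs."""

    histogram: Dict[int, int]
    n_pairs: int
    n_stitched: int
    mean: float
    sd: float
    cv: float

    @property
    def stitch_fraction(self) -> float:
        return self.n_stitched / self.n_pairs if self.n_pairs else 0.0

    @classmethod
    def from_lengths(cls, lengths: Sequence[int], n_pairs: int) -> "OverlapStats":
        hist = dict(sorted(Counter(lengths).items()))
        n = len(lengths)
        if n == 0:
            nan = float("nan")
            return cls(hist, n_pairs, 0, nan, nan, nan)
        arr = np.asarray(lengths, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std())  # population SD of the observed lengths
        cv = sd / mean if mean > 0 else float("nan")
        return cls(hist, n_pairs, n, mean, sd, cv)

    def write_histogram(self, dest) -> None:
        """Tab-separated (length, count) debug output."""
        with open(dest, "wt") as fh:
            for length, count in self.histogram.items():
                fh.write(f"{length}\t{count}\n")


def _best_placement(r1: Read, r2: Read, params: StitchParams
                    ) -> Optional[Tuple[str, int, int]]:
    """(orientation, overlap_len, mismatches) of the best placement."""
    a = encode(r1.seq)
    b = encode(reverse_complement(r2.seq))
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        return None
    vmax = min(params.max_overlap, n1, n2)
    if vmax < params.min_overlap:
        return None

    cands: List[Tuple[float, int, int, str, int]] = []

    def scan(matches: np.ndarray, orientation: str, vhi: int):
        vs = np.arange(params.min_overlap, vhi + 1)
        if len(vs) == 0:
            return
        mm = vs - matches[vs]
        dens = mm / vs
        ok = dens <= params.max_mismatch_density
        for v, m, d in zip(vs[ok], mm[ok], dens[ok]):
            # sort key: density asc, overlap desc, innie before outie
            cands.append((float(d), -int(v), 0 if orientation == "innie" else 1,
                          orientation, int(m)))

    scan(innie_matches(a, b), "innie", vmax)
    if params.allow_outies:
        ob = outie_matches(a, b)
        vhi = min(n1, n2, params.max_overlap)
        if n1 == n2:
            vhi = min(vhi, n1 - 1)  # full overlap already covered as innie
        scan(ob, "outie", vhi)

    if not cands:
        return None
    d, negv, _, orientation, m = min(cands)
    return orientation, -negv, m


def merge_pair(r1: Read, r2: Read, placement: Tuple[str, int]) -> Read:
    """Build the merged contig for a placement from :func:`best_overlap`.

    Non-overlap regions are copied verbatim from the contributing mate.  In
    the overlap: agreement keeps the base with quality max(q1, q2);
    disagreement keeps the higher-quality base (ties to read 1) with
    quality max(2, |q1 - q2|).
    """
    orientation, v = placement[0], placement[1]
    seq2 = reverse_complement(r2.seq)
    qual2 = r2.qual[::-1]
    n1, n2 = len(r1), len(r2)

    if orientation == "innie":
        left_seq, left_qual = r1.seq[: n1 - v], r1.qual[: n1 - v]
        o1s, o1q = r1.seq[n1 - v:], r1.qual[n1 - v:]
        o2s, o2q = seq2[:v], qual2[:v]
        right_seq, right_qual = seq2[v:], qual2[v:]
    else:  # outie: only the overlapping (insert) region is retained
        left_seq, left_qual = "", ()
        o1s, o1q = r1.seq[:v], r1.qual[:v]
        o2s, o2q = seq2[n2 - v:], qual2[n2 - v:]
        right_seq, right_qual = "", ()

    mid_seq = []
    mid_qual = []
    for b1, q1, b2, q2 in zip(o1s, o1q, o2s, o2q):
        if b1 == b2:
            mid_seq.append(b1)
            mid_qual.append(max(q1, q2))
        else:
            mid_seq.append(b1 if q1 >= q2 else b2)
            mid_qual.append(max(CONFLICT_QUAL_FLOOR, abs(q1 - q2)))

    return Read(
        r1.id,
        left_seq + "".join(mid_seq) + right_seq,
        tuple(left_qual) + tuple(mid_qual) + tuple(right_qual),
    )


def best_overlap(r1: Read, r2: Read,
                 params: StitchParams = StitchParams()) -> Optional[StitchResult]:
    """Merge a pair at its best qualifying overlap, or None if none exists."""
    placement = _best_placement(r1, r2, params)
    if placement is None:
        return None
    orientation, v, mm = placement
    merged = merge_pair(r1, r2, (orientation, v))
    return StitchResult(merged, v, mm, orientation)


def stitch_pairs(pairs: Iterable[Tuple[Read, Read]],
                 params: StitchParams = StitchParams()
                 ) -> List[Optional[StitchResult]]:
    return [best_overlap(r1, r2, params) for r1, r2 in pairs]


def stitch_stats(pairs: Sequence[Tuple[Read, Read]],
                 params: StitchParams = StitchParams()) -> OverlapStats:
    """Stitch every pair and summarise the merged-length distribution.

    Zero successful stitches is not an error: the statistics come back with
    ``n_stitched == 0`` and NaN mean/sd/cv for the caller to interpret.
    """
    if len(pairs) == 0:
        raise ValueError("stitch_stats requires at least one pair")
    results = stitch_pairs(pairs, params)
    lengths = [len(r.merged) for r in results if r is not None]
    return OverlapStats.from_lengths(lengths, len(pairs))
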