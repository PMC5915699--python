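"""Shared test utilities: read builders and naive reference implementations.

The naive functions here are deliberately independent, loop-based
re-derivations used as oracles against the vectorised library code.
"""

from __future__ import annotations

from itertools import product
from typing import Optional, Sequence, Tuple

import numpy as np

from autoshi.demultiplex import base_cost
from autoshi.fastq_io import Read, reverse_complement

BASES = "ACGT"


def mk(seq: str, qual=30, rid: str = "r") -> Read:
    if isinstance(qual, int):
        qual = (qual,) * len(seq)
    return Read(rid, seq, tuple(qual))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def random_read(rng: np.random.Generator, n: int, rid: str = "r") -> Read:
    return Read(rid, random_seq(rng, n),
                tuple(int(q) for q in rng.integers(2, 41, n)))


# ---------------------------------------------------------------- barcodes

def naive_mismatches(barcode: str, seq: str, offset: int = 0) -> int:
    mm = 0
    for i, b in enumerate(barcode):
        if offset + i >= len(seq):
            mm += 1
        else:
            mm += base_cost(b, seq[offset + i])
    return mm


def naive_match(read: Read, specs, max_mismatch: int, search_window: int = 0):
    """Exhaustive scorer over all specs and offsets; same tie rule."""
    scored = []
    for spec in specs:
        best = min(
            naive_mismatches(spec.barcode_fwd, read.seq, off)
            for off in range(search_window + 1)
        )
        if best <= max_mismatch:
            scored.append((best, spec.sample_id))
    if not scored:
        return None, -1
    scored.sort()
    if len(scored) > 1 and scored[1][0] == scored[0][0]:
        return None, scored[0][0]
    return scored[0][1], scored[0][0]


def brute_collides(b1: str, b2: str, max_mismatch: int) -> bool:
    """Enumerate every possible read prefix (4^L)."""
    L = max(len(b1), len(b2))
    for tup in product(BASES, repeat=L):
        s = "".join(tup)
        if (naive_mismatches(b1, s) <= max_mismatch
                and naive_mismatches(b2, s) <= max_mismatch):
            return True
    return False


# ---------------------------------------------------------------- stitching

def naive_best_placement(r1: Read, r2: Read, min_overlap: int,
                         max_overlap: int, max_density: float,
                         allow_outies: bool = False
                         ) -> Optional[Tuple[str, int, int]]:
    """All-offsets scorer: (orientation, overlap, mismatches) or None."""
    rc2 = reverse_complement(r2.seq)
    n1, n2 = len(r1.seq), len(rc2)
    best = None
    orientations = ["innie"] + (["outie"] if allow_outies else [])
    for orientation in orientations:
        for v in range(min_overlap, min(max_overlap, n1, n2) + 1):
            if orientation == "innie":
                s1, s2 = r1.seq[n1 - v:], rc2[:v]
            else:
                if v == n1 == n2:
                    continue
                s1, s2 = r1.seq[:v], rc2[n2 - v:]
            mm = sum(a != b for a, b in zip(s1, s2))
            d = mm / v
            if d <= max_density:
                key = (d, -v, 0 if orientation == "innie" else 1)
                if best is None or key < best[0]:
                    best = (key, orientation, v, mm)
    return None if best is None else best[1:]


# ------------------------------------------------------------ floor trimming

def brute_floor_trim(qual: Sequence[int], head: int, tail: int,
                     window: int) -> Tuple[int, int]:
    """Cut points (lo, hi) found by scanning all positions.

    lo is the first position whose forward window (capped at the read end)
    contains no base below the head floor; hi is the last position > lo
    whose backward window (capped at lo) is clean for the tail floor.
    """
    n = len(qual)

    def head_clean(lo):
        w = qual[lo:min(lo + window, n)]
        return bool(w) and min(w) >= head

    lo = next((i for i in range(n) if head_clean(i)), n)

    def tail_clean(hi):
        w = qual[max(hi - window, lo):hi]
        return bool(w) and min(w) >= tail

    hi = next((j for j in range(n, lo, -1) if tail_clean(j)), lo)
    return lo, hi
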