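"""Sliding quality-floor trimming plus length and mean-quality filtering.

Unlike window-*mean* trimmers, the floor rule will not tolerate even a
single base below the threshold anywhere in the terminal window: bases are
shaved one at a time from each end until every base in the window clears
the floor.  The two ends may use different floors, which is useful after
full-read-length stitching where overlaid opposing adaptors surface as
very low consensus qualities at the read ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .fastq_io import Read


@dataclass(frozen=True)
class TrimParams:
    floor_q_head: int = 20
    floor_q_tail: int = 20
    window: int = 4
    min_length: int = 1
    min_avg_q: float = 0.0

    def __post_init__(self):
        if not (0 <= self.floor_q_head <= 60 and 0 <= self.floor_q_tail <= 60):
            raise ValueError("quality floors must be in [0, 60]")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def floor_trim(read: Read, params: TrimParams) -> Read:
    """Trim both ends until the terminal windows contain no sub-floor base.

    From the 5' end: while the next ``window`` bases contain any base with
    quality below ``floor_q_head``, drop the first base; then symmetrically
    from the 3' end with ``floor_q_tail``.  When fewer than ``window`` bases
    remain, the remainder is tested as a single window.  May return an
    empty read; the output is always a contiguous substring of the input.
    """
    q = read.qual
    n = len(q)
    w = params.window
    lo, hi = 0, n
    while lo < hi:
        window = q[lo:min(lo + w, hi)]
        if min(window) >= params.floor_q_head:
            break
        lo += 1
    while hi > lo:
        window = q[max(hi - w, lo):hi]
        if min(window) >= params.floor_q_tail:
            break
        hi -= 1
    return read.cut(lo, hi)


def filter_read(read: Read, params: TrimParams) -> Optional[str]:
    """Post-trim filter; returns a drop reason or None to keep.

    Reads shorter than ``min_length`` drop as "length"; reads whose mean
    quality is strictly below ``min_avg_q`` drop as "quality" (a read
    exactly at the threshold is kept).
    """
    if len(read) < params.min_length:
        return "length"
    if params.min_avg_q > 0:
        if len(read) == 0 or read.mean_quality < params.min_avg_q:
            return "quality"
    return None
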