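"""Error-correcting barcode demultiplexing of pooled sequencing lanes.

Barcodes are compared against read prefixes by Hamming distance with IUPAC
ambiguity support: an ambiguity code in the *barcode* (including leading
runs of ``N`` used for staggered designs) matches any compatible read base
at zero cost, while an ``N`` in the *read* mismatches every non-``N``
barcode base.  A read is assigned to the unique sample with the minimal
mismatch count within the allowed budget; ties are deliberately left
unassigned, since silent misassignment is worse than read loss.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .fastq_io import (
    BarcodeSpec,
    Read,
    read_fastq,
    sanitize_sample_id,
    write_fastq,
)

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class DemuxParams:
    max_mismatch: int = 0
    #: Largest start offset scanned for the barcode (0 = prefix only).
    search_window: int = 0
    strip_barcode: bool = True

    def __post_init__(self):
        if self.max_mismatch < 0 or self.search_window < 0:
            raise ValueError("max_mismatch and search_window must be >= 0")


@dataclass
class DemuxReport:
    assigned: Dict[str, int]
    unassigned: int
    collisions: List[Tuple[str, str]]
    total: int

    def __post_init__(self):
        if sum(self.assigned.values()) + self.unassigned != self.total:
            raise ValueError("demux counts do not conserve input records")


def base_cost(barcode_char: str, read_char: str) -> int:
    """Mismatch cost of one barcode position against one read base."""
    if barcode_char == "N":
        return 0
    if read_char == "N":
        return 1
    return 0 if read_char in IUPAC_EXPAND.get(barcode_char, barcode_char) else 1


def barcode_mismatches(barcode: str, seq: str, offset: int = 0) -> int:
    """Hamming-style mismatches of a barcode against seq[offset:]."""
    mm = 0
    for i, bc in enumerate(barcode):
        j = offset + i
        if j >= len(seq):
            mm += 1  # barcode runs off the read end
        else:
            mm += base_cost(bc, seq[j])
    return mm


def match_barcode(read: Read, specs: Sequence[BarcodeSpec],
                  params: DemuxParams = DemuxParams()
                  ) -> Tuple[Optional[str], int, Read]:
    """Assign a read to a sample by its forward barcode.

    Returns (sample_id or None, mismatches of the best hit, read with the
    barcode prefix removed on assignment).  A tie between two samples at the
    minimal mismatch count leaves the read unassigned.
    """
    if not specs:
        raise ValueError("no barcode specs given")
    best: List[Tuple[int, int, BarcodeSpec]] = []  # (mm, offset, spec)
    for spec in specs:
        spec_best = None
        for off in range(params.search_window + 1):
            mm = barcode_mismatches(spec.barcode_fwd, read.seq, off)
            if spec_best is None or mm < spec_best[0]:
                spec_best = (mm, off)
        if spec_best is not None and spec_best[0] <= params.max_mismatch:
            best.append((spec_best[0], spec_best[1], spec))
    if not best:
        return None, -1, read
    best.sort(key=lambda t: t[0])
    min_mm = best[0][0]
    hits = [t for t in best if t[0] == min_mm]
    if len(hits) > 1:
        return None, min_mm, read  # ambiguous
    mm, off, spec = hits[0]
    out = read
    if params.strip_barcode:
        out = read.cut(off + len(spec.barcode_fwd))
    return spec.sample_id, mm, out


def _pair_confusable(b1: str, b2: str, max_mismatch: int) -> bool:
    """Exact test: does a read prefix exist within max_mismatch of both?

    Positionwise dynamic programme over the four concrete bases; tracks, for
    every achievable mismatch total against b1, the minimal total against
    b2.  Equivalent to brute force over all 4^L prefixes but polynomial.
    """
    L = max(len(b1), len(b2))
    best = {0: 0}  # cost vs b1 -> minimal cost vs b2
    for i in range(L):
        step = set()
        for x in "ACGT":
            c1 = base_cost(b1[i], x) if i < len(b1) else 0
            c2 = base_cost(b2[i], x) if i < len(b2) else 0
            step.add((c1, c2))
        nxt: Dict[int, int] = {}
        for c1, c2 in best.items():
            for d1, d2 in step:
                k = c1 + d1
                if k > max_mismatch:
                    continue
                v = c2 + d2
                if k not in nxt or v < nxt[k]:
                    nxt[k] = v
        if not nxt:
            return False
        best = nxt
    return any(v <= max_mismatch for v in best.values())


def check_collisions(specs: Sequence[BarcodeSpec], max_mismatch: int
                     ) -> List[Tuple[str, str]]:
    """Sample pairs whose barcodes the mismatch budget could confuse.

    A pair collides when some read prefix lies within ``max_mismatch`` of
    both forward barcodes (and, where both samples carry reverse barcodes,
    of both reverse barcodes too).
    """
    if not specs:
        raise ValueError("no barcode specs given")
    out = []
    for s1, s2 in itertools.combinations(specs, 2):
        if not _pair_confusable(s1.barcode_fwd, s2.barcode_fwd, max_mismatch):
            continue
        if s1.barcode_rev and s2.barcode_rev:
            if not _pair_confusable(s1.barcode_rev, s2.barcode_rev, max_mismatch):
                continue
        out.append((s1.sample_id, s2.sample_id))
    return sorted(out)


def _match_pair(r1: Read, r2: Optional[Read], specs: Sequence[BarcodeSpec],
                params: DemuxParams
                ) -> Tuple[Optional[str], Read, Optional[Read]]:
    """Joint assignment of a mate pair (or single read when r2 is None)."""
    best: List[Tuple[int, BarcodeSpec]] = []
    for spec in specs:
        mm1 = min(
            barcode_mismatches(spec.barcode_fwd, r1.seq, off)
            for off in range(params.search_window + 1)
        )
        if mm1 > params.max_mismatch:
            continue
        total = mm1
        if spec.barcode_rev:
            if r2 is None:
                raise ValueError(
                    f"sample {spec.sample_id!r} has a reverse barcode but the "
                    "input is single-end"
                )
            mm2 = min(
                barcode_mismatches(spec.barcode_rev, r2.seq, off)
                for off in range(params.search_window + 1)
            )
            if mm2 > params.max_mismatch:
                continue  # both mates must match the same sample
            total += mm2
        best.append((total, spec))
    if not best:
        return None, r1, r2
    best.sort(key=lambda t: t[0])
    if len(best) > 1 and best[1][0] == best[0][0]:
        return None, r1, r2  # ambiguous
    spec = best[0][1]
    out1, out2 = r1, r2
    if params.strip_barcode:
        out1 = r1.cut(len(spec.barcode_fwd))
        if r2 is not None and spec.barcode_rev:
            out2 = r2.cut(len(spec.barcode_rev))
    return spec.sample_id, out1, out2


def demultiplex_run(fastq_paths: Sequence, specs: Sequence[BarcodeSpec],
                    params: DemuxParams, out_dir,
                    offset: int = 33) -> DemuxReport:
    """Split one pooled FASTQ file (or split-file pair) by sample barcode.

    Writes ``<sample>.R1.fastq`` / ``<sample>.R2.fastq`` (or ``.fastq`` for
    single-end) plus an ``unassigned`` pool and a tab-separated report.
    Mate files must be record-synchronised; a length mismatch is a hard
    error.  Assigned + unassigned record counts always equal the input
    count (paired files counted per mate).
    """
    if len(fastq_paths) not in (1, 2):
        raise ValueError("expected one FASTQ file or one mate pair")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paired = len(fastq_paths) == 2

    names = {}
    for spec in specs:
        safe = sanitize_sample_id(spec.sample_id)
        if safe in names.values():
            raise ValueError(f"sample name collision after sanitization: {safe!r}")
        names[spec.sample_id] = safe
    names[None] = "unassigned"

    collisions = check_collisions(specs, params.max_mismatch)

    buckets: Dict[Optional[str], List[Read]] = {k: [] for k in names}
    counts: Counter = Counter()
    total = 0

    it1 = read_fastq(fastq_paths[0], offset)
    it2 = read_fastq(fastq_paths[1], offset) if paired else None
    for r1 in it1:
        r2 = None
        if paired:
            r2 = next(it2, None)
            if r2 is None:
                raise ValueError("mate-count mismatch between paired files")
        sample, o1, o2 = _match_pair(r1, r2, specs, params)
        buckets[sample].append(o1)
        total += 1
        if paired:
            buckets[sample].append(o2)
            total += 1
        counts[sample] += 2 if paired else 1
    if paired and next(it2, None) is not None:
        raise ValueError("mate-count mismatch between paired files")

    for sample, reads in buckets.items():
        safe = names[sample]
        if paired:
            write_fastq(reads[0::2], out_dir / f"{safe}.R1.fastq", offset)
            write_fastq(reads[1::2], out_dir / f"{safe}.R2.fastq", offset)
        else:
            write_fastq(reads, out_dir / f"{safe}.fastq", offset)

    assigned = {s.sample_id: counts.get(s.sample_id, 0) for s in specs}
    report = DemuxReport(assigned, counts.get(None, 0), collisions, total)
    with open(out_dir / "demux_report.tsv", "wt") as fh:
        fh.write("sample\trecords\n")
        for sample, n in assigned.items():
            fh.write(f"{sample}\t{n}\n")
        fh.write(f"unassigned\t{report.unassigned}\n")
        for a, b in collisions:
            fh.write(f"#collision\t{a}<->{b}\n")
    return report
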