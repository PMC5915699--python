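"""FASTQ/FASTA I/O, PHRED-offset detection, oligos parsing and subsampling.

The FASTQ reader is deliberately strict: records must occupy exactly four
lines (no word wrap), and any structural defect is a hard error that names
the offending record rather than a silent mis-parse. Compressed input is
rejected with an actionable message.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Sequence, Tuple, Union

log = logging.getLogger(__name__)

#: Highest PHRED value kept after decoding; larger encoded values are clamped.
QUAL_CAP = 60

PHRED33 = 33
PHRED64 = 64

IUPAC_ALPHABET = frozenset("ACGTURYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")

Source = Union[str, Path, IO[str]]


class FastqFormatError(ValueError):
    """Raised for structurally invalid FASTQ input."""


class OligosFormatError(ValueError):
    """Raised for invalid MOTHUR oligos input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_sample_id(name: str) -> str:
    """Map a sample name onto a filesystem- and FASTA-header-safe token.

    Every non-alphanumeric character becomes ``.`` (so ``gut-3/b`` ->
    ``gut.3.b``).
    """
    return re.sub(r"[^A-Za-z0-9]", ".", name)


@dataclass(frozen=True)
class Read:
    """A single sequencing record with decoded per-base PHRED qualities."""

    id: str
    seq: str
    qual: Tuple[int, ...]

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def cut(self, start: int = 0, stop: int | None = None) -> "Read":
        """Contiguous sub-read; bases and qualities are never edited."""
        return Read(self.id, self.seq[start:stop], self.qual[start:stop])

    @property
    def mean_quality(self) -> float:
        if not self.qual:
            return float("nan")
        return sum(self.qual) / len(self.qual)


@dataclass(frozen=True)
class BarcodeSpec:
    """One MOTHUR oligos entry: a sample and its (optionally paired) barcode."""

    sample_id: str
    barcode_fwd: str
    barcode_rev: str = ""

    def __post_init__(self):
        if not self.barcode_fwd:
            raise OligosFormatError(f"sample {self.sample_id!r}: empty barcode")
        for bc in (self.barcode_fwd, self.barcode_rev):
            bad = set(bc) - IUPAC_ALPHABET
            if bad:
                raise OligosFormatError(
                    f"sample {self.sample_id!r}: non-IUPAC characters "
                    f"{sorted(bad)} in barcode {bc!r}"
                )


def _reject_compressed(path: Path) -> None:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic in (b"\x1f\x8b", b"BZ", b"PK"):
        raise FastqFormatError(
            f"{path}: compressed FASTQ is not supported; extract the files "
            "first (e.g. `gunzip *`)"
        )


def _open_text(source: Source):
    """Return (handle, needs_close)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        _reject_compressed(path)
        return open(path, "rt"), True
    return source, False


def iter_raw_records(source: Source) -> Iterator[Tuple[str, str, str]]:
    """Yield (id, seq, raw_quality_string) from strict 4-line FASTQ."""
    handle, needs_close = _open_text(source)
    try:
        idx = 0
        while True:
            header = handle.readline()
            if not header:
                return
            idx += 1
            lines = [header, handle.readline(), handle.readline(), handle.readline()]
            if "" in lines[1:]:
                raise FastqFormatError(
                    f"record {idx}: truncated record (line count not a "
                    "multiple of 4)"
                )
            header, seq, plus, qual = (ln.rstrip("\n") for ln in lines)
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"record {idx}: header does not start with '@' "
                    f"(wrapped records are not supported): {header!r}"
                )
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"record {idx}: separator line does not start with '+' "
                    f"(wrapped records are not supported): {plus!r}"
                )
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"record {idx}: sequence length {len(seq)} != quality "
                    f"length {len(qual)}"
                )
            yield header[1:], seq, qual
    finally:
        if needs_close:
            handle.close()


def decode_quality(raw: str, offset: int, *, _warned=[False]) -> Tuple[int, ...]:
    vals = []
    for ch in raw:
        q = ord(ch) - offset
        if q < 0:
            raise FastqFormatError(
                f"quality character {ch!r} decodes below 0 at PHRED+{offset}; "
                "wrong offset?"
            )
        if q > QUAL_CAP:
            if not _warned[0]:
                log.warning(
                    "quality value %d exceeds %d; clamping (reported once)",
                    q, QUAL_CAP,
                )
                _warned[0] = True
            q = QUAL_CAP
        vals.append(q)
    return tuple(vals)


def read_fastq(source: Source, offset: int = PHRED33) -> Iterator[Read]:
    """Iterate decoded reads from a strict 4-line FASTQ stream or path."""
    for rid, seq, raw in iter_raw_records(source):
        yield Read(rid, seq, decode_quality(raw, offset))


def write_fastq(reads: Iterable[Read], dest: Source, offset: int = PHRED33) -> int:
    handle, needs_close = (open(dest, "wt"), True) if isinstance(dest, (str, Path)) else (dest, False)
    n = 0
    try:
        for r in reads:
            qual = "".join(chr(q + offset) for q in r.qual)
            handle.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            n += 1
    finally:
        if needs_close:
            handle.close()
    return n


def write_fasta(records: Iterable[Tuple[str, str]], dest: Source) -> int:
    """Write (header, sequence) pairs as unwrapped FASTA."""
    handle, needs_close = (open(dest, "wt"), True) if isinstance(dest, (str, Path)) else (dest, False)
    n = 0
    try:
        for header, seq in records:
            handle.write(f">{header}\n{seq}\n")
            n += 1
    finally:
        if needs_close:
            handle.close()
    return n


def detect_phred_offset(quality_strings: Iterable[str], max_records: int = 1000) -> int:
    """Infer the PHRED encoding offset (33 or 64) from raw quality strings.

    Any ASCII code below 59 forces PHRED+33 (impossible under +64); all codes
    >= 64 with at least one above 74 indicate PHRED+64.  The ambiguous band
    [64, 74] defaults to 33 with a warning.
    """
    lo, hi = 255, 0
    n = 0
    for raw in quality_strings:
        if n >= max_records:
            break
        if raw:
            codes = [ord(c) for c in raw]
            lo = min(lo, min(codes))
            hi = max(hi, max(codes))
            n += 1
    if n == 0:
        raise FastqFormatError("cannot detect PHRED offset: no quality data")
    if lo < 59:
        return PHRED33
    if lo >= 64 and hi > 74:
        return PHRED64
    log.warning(
        "ambiguous quality range [%d, %d]; defaulting to PHRED+33", lo, hi
    )
    return PHRED33


def detect_phred_offset_file(path: Source, max_records: int = 1000) -> int:
    return detect_phred_offset(
        (raw for _, _, raw in iter_raw_records(path)), max_records
    )


def parse_oligos(source: Source) -> List[BarcodeSpec]:
    """Parse a MOTHUR-format oligos file into barcode specifications.

    Lines starting with ``barcode`` carry one or two barcode columns followed
    by the sample id; ``primer`` lines and ``#`` comments are ignored.
    """
    handle, needs_close = _open_text(source)
    specs: List[BarcodeSpec] = []
    seen = set()
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            kind = fields[0].lower()
            if kind == "primer":
                continue
            if kind != "barcode":
                continue
            if len(fields) == 3:
                _, fwd, sample = fields
                rev = ""
            elif len(fields) == 4:
                _, fwd, rev, sample = fields
            else:
                raise OligosFormatError(
                    f"line {lineno}: expected 'barcode <fwd> [rev] <sample>', "
                    f"got {line!r}"
                )
            if sample in seen:
                raise OligosFormatError(
                    f"line {lineno}: duplicate sample id {sample!r}"
                )
            seen.add(sample)
            specs.append(BarcodeSpec(sample, fwd.upper(), rev.upper()))
    finally:
        if needs_close:
            handle.close()
    if not specs:
        raise OligosFormatError("no barcode lines found in oligos file")
    return specs


def subsample(path: Source, n: int = 1000, offset: int | None = None) -> List[Read]:
    """Return the first min(n, total) records of a FASTQ file.

    Head-of-file sampling is used so repeated calls are identical.  When
    ``offset`` is None the PHRED offset is auto-detected from the sampled
    records themselves.
    """
    if n < 1:
        raise ValueError(f"subsample size must be >= 1, got {n}")
    raws: List[Tuple[str, str, str]] = []
    for rec in iter_raw_records(path):
        raws.append(rec)
        if len(raws) >= n:
            break
    if offset is None:
        offset = detect_phred_offset((raw for _, _, raw in raws), n) if raws else PHRED33
    return [Read(rid, seq, decode_quality(raw, offset)) for rid, seq, raw in raws]
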