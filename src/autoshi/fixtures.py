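"""Synthetic sequencing-run generator with a recorded ground truth.

Simulates the data regimes the learner has to tell apart: amplicon runs
(narrow insert-length distribution, read-through into the opposing adaptor
when the read is longer than the insert), shotgun runs (broad insert
distribution), long uniform "contaminant" fragments emulating PhiX-like
control sequences, barcoded multiplexed lanes, and a head/body/tail
quality profile.  Sequencing errors are per-base substitutions drawn with
probability 10^(-q/10) from the assigned quality, so the quality values and
the error process are self-consistent.  Output is fully determined by the
seed; a tab-separated truth table records, per fragment, the sample, insert
length, appended adaptor lengths, the error-free reads and the injected
errors, so every read can be reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .adaptor_clip import AdaptorSet
from .fastq_io import BarcodeSpec, Read, reverse_complement, write_fastq
from .demultiplex import IUPAC_EXPAND

_BASES = "ACGT"

TRUTH_COLUMNS = (
    "read_id", "sample", "insert_len", "adaptor_len_r1", "adaptor_len_r2",
    "clean_r1", "clean_r2", "errors_r1", "errors_r2",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth description of one synthetic run (seed mandatory)."""

    seed: int
    n_fragments: int = 1000
    read_len: int = 100
    insert_mean: float = 150.0
    insert_sd: float = 21.0
    adaptor: str = "None"
    #: Fraction of fragments forced short enough for adaptor read-through.
    spike_fraction: float = 0.0
    barcodes: Tuple[BarcodeSpec, ...] = ()
    barcode_error_rate: float = 0.0
    q_head: float = 33.0
    q_body: float = 36.0
    q_tail: float = 30.0
    q_sd: float = 3.0
    terminus_len: int = 10
    contaminant_fraction: float = 0.0
    contaminant_range: Tuple[int, int] = (350, 450)
    name: str = "sim"
    phred_offset: int = 33

    def __post_init__(self):
        for frac in (self.spike_fraction, self.barcode_error_rate,
                     self.contaminant_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        if self.read_len < 1 or self.n_fragments < 1:
            raise ValueError("read_len and n_fragments must be >= 1")


def _readthrough_adaptors(aset: AdaptorSet) -> Tuple[str, str]:
    """(r1 read-through, r2 read-through) for a built-in style set.

    A short fragment makes read 1 run into the reverse complement of the
    adapter ligated on the read-2 side and vice versa.  Sets shipping
    explicit ``*_rc`` entries provide these directly; otherwise they are
    derived from the ``Prefix*/1`` / ``Prefix*/2`` adapters.
    """
    rc_entries = {}
    prefixes = {}
    for label, seq in aset.sequences:
        if label.endswith("_rc"):
            stem = label[:-3]
            if stem.endswith("1"):
                rc_entries["1"] = seq
            elif stem.endswith("2"):
                rc_entries["2"] = seq
        elif "Prefix" in label and "/" in label:
            prefixes[label.rsplit("/", 1)[1]] = seq
    if "1" in rc_entries and "2" in rc_entries:
        return rc_entries["2"], rc_entries["1"]
    if "1" in prefixes and "2" in prefixes:
        return (reverse_complement(prefixes["2"]),
                reverse_complement(prefixes["1"]))
    raise ValueError(
        f"adaptor set {aset.name!r} lacks *_rc and Prefix*/1+2 entries"
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _concrete_barcode(rng: np.random.Generator, barcode: str) -> str:
    out = []
    for ch in barcode:
        if ch in _BASES:
            out.append(ch)
        else:
            opts = IUPAC_EXPAND[ch]
            out.append(opts[int(rng.integers(0, len(opts)))])
    return "".join(out)


def _quality_profile(rng: np.random.Generator, spec: FixtureSpec,
                     n: int) -> np.ndarray:
    means = np.full(n, spec.q_body)
    k = min(spec.terminus_len, n)
    means[:k] = spec.q_head
    means[n - k:] = spec.q_tail
    q = np.rint(rng.normal(means, spec.q_sd)).astype(int)
    return np.clip(q, 2, 40)


def _apply_errors(rng: np.random.Generator, seq: str, qual: np.ndarray
                  ) -> Tuple[str, str]:
    """Substitute bases with probability 10^(-q/10); returns (seq, log)."""
    p = 10.0 ** (-qual / 10.0)
    hits = np.flatnonzero(rng.random(len(seq)) < p)
    if len(hits) == 0:
        return seq, ""
    chars = list(seq)
    log = []
    for i in hits:
        alts = [b for b in _BASES if b != chars[i]]
        chars[i] = alts[rng.integers(0, 3)]
        log.append(f"{i}:{chars[i]}")
    return "".join(chars), ";".join(log)


def generate_run(spec: FixtureSpec, out_dir) -> Dict[str, Path]:
    """Write a paired synthetic run plus its truth table.

    Returns paths under keys "r1", "r2" and "truth".  Reads are built as
    [barcode +] insert [+ opposing-adaptor read-through + random filler],
    truncated to ``read_len``; R2 reads the reverse complement strand.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    rt1 = rt2 = ""
    if spec.adaptor != "None":
        rt1, rt2 = _readthrough_adaptors(AdaptorSet.load(spec.adaptor))

    reads1: List[Read] = []
    reads2: List[Read] = []
    truth_rows: List[Tuple] = []

    for i in range(spec.n_fragments):
        if spec.contaminant_fraction and rng.random() < spec.contaminant_fraction:
            lo, hi = spec.contaminant_range
            insert_len = int(rng.integers(lo, hi + 1))
            sample_tag = "contaminant"
        else:
            insert_len = max(1, int(round(rng.normal(spec.insert_mean,
                                                     spec.insert_sd))))
            sample_tag = ""
            if (spec.spike_fraction and insert_len >= spec.read_len
                    and rng.random() < spec.spike_fraction):
                insert_len = int(spec.read_len * rng.uniform(0.4, 0.85))

        insert = _random_seq(rng, insert_len)

        bc1 = bc2 = ""
        sample = sample_tag or "pool"
        if spec.barcodes:
            bspec = spec.barcodes[int(rng.integers(0, len(spec.barcodes)))]
            sample = sample_tag or bspec.sample_id
            bc1 = _concrete_barcode(rng, bspec.barcode_fwd)
            if spec.barcode_error_rate:
                bc1, _ = _mutate(rng, bc1, spec.barcode_error_rate)
            if bspec.barcode_rev:
                bc2 = _concrete_barcode(rng, bspec.barcode_rev)
                if spec.barcode_error_rate:
                    bc2, _ = _mutate(rng, bc2, spec.barcode_error_rate)

        def build(template: str, adaptor: str, bc: str) -> Tuple[str, int]:
            body = template + adaptor
            n_adapt = max(0, min(len(adaptor), spec.read_len - len(bc) - len(template)))
            need = spec.read_len - len(bc)
            if len(body) < need:
                body += _random_seq(rng, need - len(body))
            return bc + body[:need], n_adapt

        clean1, na1 = build(insert, rt1, bc1)
        clean2, na2 = build(reverse_complement(insert), rt2, bc2)

        q1 = _quality_profile(rng, spec, spec.read_len)
        q2 = _quality_profile(rng, spec, spec.read_len)
        seq1, err1 = _apply_errors(rng, clean1, q1)
        seq2, err2 = _apply_errors(rng, clean2, q2)

        rid = f"{spec.name}.{i}"
        reads1.append(Read(rid, seq1, tuple(int(x) for x in q1)))
        reads2.append(Read(rid, seq2, tuple(int(x) for x in q2)))
        truth_rows.append(
            (rid, sample, insert_len, na1, na2, clean1, clean2, err1, err2)
        )

    paths = {
        "r1": out_dir / f"{spec.name}_R1.fastq",
        "r2": out_dir / f"{spec.name}_R2.fastq",
        "truth": out_dir / f"{spec.name}_truth.tsv",
    }
    write_fastq(reads1, paths["r1"], spec.phred_offset)
    write_fastq(reads2, paths["r2"], spec.phred_offset)
    with open(paths["truth"], "wt") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for row in truth_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return paths


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> Tuple[str, str]:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    chars = list(seq)
    log = []
    for i in hits:
        alts = [b for b in _BASES if b != chars[i]]
        chars[i] = alts[rng.integers(0, 3)]
        log.append(f"{i}:{chars[i]}")
    return "".join(chars), ";".join(log)


def load_truth(path) -> List[Dict[str, str]]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows
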