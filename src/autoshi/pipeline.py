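"""Orchestration of the full QC run and combined-FASTA output.

Stage order: demultiplex (when an oligos file is present) -> adaptor clip
-> stitch -> quality-floor trim -> length/mean-quality filter (including
the amplicon merged-length band, when learned) -> format conversion.
Every stage can be switched off; the run is deterministic for a given
configuration, and multi-threaded runs emit records in the same order as
single-threaded ones.
"""

from __future__ import annotations

import logging
import shutil
from collections import Counter
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from . import adaptor_clip
from .adaptor_clip import AdaptorSet, ClipParams
from .demultiplex import DemuxParams, demultiplex_run
from .fastq_io import (
    Read,
    detect_phred_offset_file,
    iter_raw_records,
    parse_oligos,
    read_fastq,
    sanitize_sample_id,
    write_fasta,
    write_fastq,
)
from .floor_trimmer import TrimParams, filter_read, floor_trim
from .learn import LearnedParams, detect_pairs, _replace_last
from .stitcher import StitchParams, stitch_pairs

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single source of truth for every pipeline flag.

    Defaults suit an adaptor-free paired-end workload where stitching is
    assumed possible; ``from_learned`` overrides them with an inferred
    parameterization.
    """

    input_dir: Union[str, Path]
    output_dir: Union[str, Path]
    single_end: Optional[bool] = None  # None = auto-detect from file names
    oligos: Optional[Union[str, Path]] = None  # None = use oligos.txt if present
    adaptor: str = "None"
    flash: bool = True  # stitch pairs (flag name kept for CLI parity)
    allow_outies: bool = False
    min_overlap: int = 10
    max_overlap: int = 700
    max_mismatch_density: float = 0.25
    trim: bool = True
    trim_qual: int = 20
    trim_qual_head: Optional[int] = None  # override per end
    trim_qual_tail: Optional[int] = None
    window: int = 4
    filter: bool = True
    filter_qual: float = 25.0
    filter_length: int = 36
    #: Inclusive merged-length band for amplicon runs (None = no band).
    length_band: Optional[Tuple[int, int]] = None
    combine_fasta: bool = True
    threads: int = 1
    phred: Optional[int] = None  # None = auto-detect
    max_barcode_mismatch: int = 1
    clip_params: ClipParams = field(default_factory=ClipParams)

    @classmethod
    def from_learned(cls, learned: LearnedParams, input_dir, output_dir,
                     **overrides) -> "RunConfig":
        cfg = cls(
            input_dir=input_dir,
            output_dir=output_dir,
            single_end=learned.single_end,
            adaptor=learned.adaptor,
            flash=learned.do_stitch,
            allow_outies=learned.allow_outies,
            trim_qual=learned.trim_qual,
            filter_qual=float(learned.filter_qual),
            length_band=(
                (learned.min_overlap_bound, learned.max_overlap_bound)
                if learned.amplicon_mode else None
            ),
            phred=learned.phred,
        )
        return replace(cfg, **overrides)


@dataclass
class RunReport:
    """Per-stage record accounting for one pipeline run."""

    stage_counts: Dict[str, Tuple[int, int]]  # stage -> (records in, out)
    drops: Counter
    per_sample: Dict[str, int]
    params_line: str
    n_input: int = 0
    n_output: int = 0

    def conserved(self) -> bool:
        return self.n_input == self.n_output + sum(self.drops.values())


def combine_to_fasta(per_sample, out_path) -> int:
    """Pool per-sample reads into one FASTA with ``<sample>_<serial>`` headers.

    ``per_sample`` maps sample names to lists of reads or to FASTQ/FASTA
    paths.  Sample names are sanitized (non-alphanumeric -> "."); a
    collision after sanitization is a hard error.  Samples are emitted in
    sorted order with 0-based per-sample serials, reads in file order.
    """
    sanitized: Dict[str, str] = {}
    for name in per_sample:
        safe = sanitize_sample_id(name)
        if safe in sanitized.values():
            raise ValueError(
                f"sample name collision after sanitization: {safe!r}"
            )
        sanitized[name] = safe

    def records():
        for name in sorted(per_sample, key=lambda n: sanitized[n]):
            source = per_sample[name]
            if isinstance(source, (str, Path)):
                seqs = (r.seq for r in read_fastq(source))
            else:
                seqs = (r.seq for r in source)
            for serial, seq in enumerate(seqs):
                yield f"{sanitized[name]}_{serial}", seq

    return write_fasta(records(), out_path)


def _count_records(path) -> int:
    return sum(1 for _ in iter_raw_records(path))


def _unit_sample_name(fname: str, patterns) -> str:
    name = Path(fname).stem
    return sanitize_sample_id(name.strip("._-"))


def _process_unit(sample: str, reads1: List[Read],
                  reads2: Optional[List[Read]], cfg: RunConfig,
                  aset: AdaptorSet) -> Tuple[List, Counter, Dict]:
    """QC one sample; returns (surviving records, drops, stage in/out)."""
    drops: Counter = Counter()
    stages: Dict[str, Tuple[int, int]] = {}
    paired = reads2 is not None
    n_in = len(reads1) + (len(reads2) if paired else 0)

    # --- adaptor clipping (record count preserved) ---
    if aset:
        if paired:
            pairs = [
                adaptor_clip.clip_pair_palindrome(a, b, aset, cfg.clip_params)
                for a, b in zip(reads1, reads2)
            ]
            reads1 = [p[0] for p in pairs]
            reads2 = [p[1] for p in pairs]
        else:
            reads1 = [adaptor_clip.clip_read(r, aset, cfg.clip_params)
                      for r in reads1]
    stages["clip"] = (n_in, n_in)

    # --- stitching ---
    if paired and cfg.flash:
        sparams = StitchParams(cfg.min_overlap, cfg.max_overlap,
                               cfg.max_mismatch_density, cfg.allow_outies)
        results = stitch_pairs(zip(reads1, reads2), sparams)
        merged: List[Read] = []
        for res in results:
            if res is None:
                drops["unstitched"] += 2
            else:
                merged.append(res.merged)
                drops["stitched_mate_merged"] += 1
        stages["stitch"] = (n_in, len(merged))
        records: List[Tuple[Read, ...]] = [(r,) for r in merged]
    elif paired:
        records = list(zip(reads1, reads2))
        stages["stitch"] = (n_in, n_in)
    else:
        records = [(r,) for r in reads1]
        stages["stitch"] = (n_in, n_in)

    # --- floor trimming (record count preserved; reads may empty) ---
    n_records = sum(len(t) for t in records)
    if cfg.trim:
        head = cfg.trim_qual_head if cfg.trim_qual_head is not None else cfg.trim_qual
        tail = cfg.trim_qual_tail if cfg.trim_qual_tail is not None else cfg.trim_qual
        tparams = TrimParams(head, tail, cfg.window)
        records = [tuple(floor_trim(r, tparams) for r in t) for t in records]
    stages["trim"] = (n_records, n_records)

    # --- filtering (length, mean quality, amplicon band); a failing mate
    # drops the whole record so pairs stay synchronised ---
    kept: List[Tuple[Read, ...]] = []
    fparams = TrimParams(0, 0, cfg.window, cfg.filter_length, cfg.filter_qual)
    for t in records:
        reason = None
        if cfg.filter:
            for r in t:
                reason = filter_read(r, fparams)
                if reason:
                    break
        if reason is None and cfg.length_band is not None:
            lo, hi = cfg.length_band
            if any(not (lo <= len(r) <= hi) for r in t):
                reason = "length_band"
        if reason is None:
            kept.append(t)
        else:
            drops[reason] += len(t)
    stages["filter"] = (n_records, sum(len(t) for t in kept))

    return kept, drops, stages


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the configured QC run; returns the record-accounting report."""
    input_dir = Path(cfg.input_dir)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    free = shutil.disk_usage(out_dir).free
    in_size = sum(f.stat().st_size for f in input_dir.glob("*.fastq"))
    if free < 2 * in_size:
        log.warning(
            "low disk space: %d bytes free for ~%d bytes of input "
            "(recommend >= 2x input size)", free, in_size,
        )

    fastqs = sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in {".fastq", ".fq"}
    )
    if not fastqs:
        raise FileNotFoundError(f"no FASTQ files in {input_dir}")

    offset = cfg.phred
    if offset is None:
        offset = detect_phred_offset_file(fastqs[0])

    pairing = None
    if cfg.single_end is not True:
        pairing = detect_pairs([p.name for p in fastqs])
        if cfg.single_end is False and pairing is None:
            raise ValueError("paired mode forced but file names do not pair")
    paired = pairing is not None

    oligos = Path(cfg.oligos) if cfg.oligos else input_dir / "oligos.txt"
    n_input = sum(_count_records(p) for p in fastqs)

    # --- build per-sample work units ---
    units: List[Tuple[str, Path, Optional[Path]]] = []
    if oligos.exists():
        specs = parse_oligos(oligos)
        demux_dir = out_dir / "demux"
        if paired:
            if len(pairing) != 1:
                raise ValueError(
                    "demultiplexing expects a single pooled file pair"
                )
            (f1, f2), = pairing.values()
            demultiplex_run([input_dir / f1, input_dir / f2], specs,
                            DemuxParams(cfg.max_barcode_mismatch),
                            demux_dir, offset)
            for spec in specs:
                safe = sanitize_sample_id(spec.sample_id)
                units.append((safe, demux_dir / f"{safe}.R1.fastq",
                              demux_dir / f"{safe}.R2.fastq"))
        else:
            if len(fastqs) != 1:
                raise ValueError("demultiplexing expects a single pooled file")
            demultiplex_run([fastqs[0]], specs,
                            DemuxParams(cfg.max_barcode_mismatch),
                            demux_dir, offset)
            for spec in specs:
                safe = sanitize_sample_id(spec.sample_id)
                units.append((safe, demux_dir / f"{safe}.fastq", None))
        n_unassigned = (
            _count_records(demux_dir / "unassigned.R1.fastq")
            + _count_records(demux_dir / "unassigned.R2.fastq")
            if paired else _count_records(demux_dir / "unassigned.fastq")
        )
    else:
        n_unassigned = 0
        if paired:
            for base in sorted(pairing):
                f1, f2 = pairing[base]
                units.append((sanitize_sample_id(base),
                              input_dir / f1, input_dir / f2))
        else:
            for f in fastqs:
                units.append((_unit_sample_name(f.name, None), f, None))

    aset = AdaptorSet.load(cfg.adaptor)

    def work(unit):
        sample, p1, p2 = unit
        reads1 = list(read_fastq(p1, offset))
        reads2 = list(read_fastq(p2, offset)) if p2 is not None else None
        return _process_unit(sample, reads1, reads2, cfg, aset)

    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            results = list(pool.map(work, units))
    else:
        results = [work(u) for u in units]

    # --- merge accounting and write outputs in deterministic order ---
    drops: Counter = Counter()
    if n_unassigned:
        drops["unassigned_barcode"] = n_unassigned
    stage_counts: Dict[str, Tuple[int, int]] = {}
    per_sample: Dict[str, int] = {}
    sample_records: Dict[str, List[Tuple[Read, ...]]] = {}

    for (sample, _, _), (kept, udrops, ustages) in zip(units, results):
        drops.update(udrops)
        for stage, (i, o) in ustages.items():
            pi, po = stage_counts.get(stage, (0, 0))
            stage_counts[stage] = (pi + i, po + o)
        sample_records[sample] = kept
        per_sample[sample] = sum(len(t) for t in kept)

    n_output = sum(per_sample.values())

    if cfg.combine_fasta:
        flat = {
            s: [r for t in recs for r in t]
            for s, recs in sample_records.items()
        }
        combine_to_fasta(flat, out_dir / "combined_seqs.fna")
    else:
        for sample in sorted(sample_records):
            recs = sample_records[sample]
            if recs and len(recs[0]) == 2:
                write_fastq((t[0] for t in recs),
                            out_dir / f"{sample}.R1.fastq", offset)
                write_fastq((t[1] for t in recs),
                            out_dir / f"{sample}.R2.fastq", offset)
            else:
                write_fastq((r for t in recs for r in t),
                            out_dir / f"{sample}.fastq", offset)

    params_line = (
        f"{'-SE ' if not paired else ''}--adaptor {cfg.adaptor} "
        f"--flash {cfg.flash and paired} --allow_outies {cfg.allow_outies} "
        f"--filter_qual {cfg.filter_qual:g} --trim_qual {cfg.trim_qual}"
    )
    report = RunReport(stage_counts, drops, per_sample, params_line,
                       n_input, n_output)
    with open(out_dir / "run.log", "wt") as fh:
        fh.write(f"parameters: {params_line}\n")
        fh.write(f"input records: {n_input}\noutput records: {n_output}\n")
        for stage, (i, o) in stage_counts.items():
            fh.write(f"stage {stage}: {i} -> {o}\n")
        for reason, n in sorted(drops.items()):
            fh.write(f"dropped ({reason}): {n}\n")
        for sample, n in sorted(per_sample.items()):
            fh.write(f"sample {sample}: {n}\n")
    if not report.conserved():
        raise AssertionError(
            "record accounting failed: "
            f"{n_input} != {n_output} + {sum(drops.values())}"
        )
    return report
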