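"""Adaptor library, 3' clipping, pair read-through removal and set detection.

Two clipping modes are provided, mirroring common practice for Illumina
data: *simple* mode places each adaptor semi-globally against the 3' end of
a single read, while *palindrome* mode detects read-through on a mate pair
by overlapping read 1 with the reverse complement of read 2 and confirming
that the overhanging bases look like an adaptor from the active set.

Adaptor sets ship as plain FASTA files inside the package and are
user-replaceable: any FASTA path can be used wherever a built-in set name is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

from ._align import encode, outie_matches, semi_global_scores
from .fastq_io import Read, reverse_complement

#: Built-in adaptor sets, in canonical (lexicographic) order.
BUILTIN_NAMES = ("Nextera", "TruSeq2", "TruSeq3", "TruSeq3-2")

_BUILTIN_FILES = {
    "Nextera": "NexteraPE-PE.fa",
    "TruSeq2": "TruSeq2-PE.fa",
    "TruSeq3": "TruSeq3-PE.fa",
    "TruSeq3-2": "TruSeq3-PE-2.fa",
}

MIN_ADAPTOR_LEN = 8

#: Fraction of bases the best candidate must remove for a set to be
#: reported at all; below this the data are declared adaptor-free ("None").
DEFAULT_MIN_GAIN = 0.0025


@dataclass(frozen=True)
class ClipParams:
    """Scoring thresholds for adaptor clipping (+1 match / -1 mismatch)."""

    seed_mismatches: int = 2
    min_match_score: int = 12
    min_palindrome_score: int = 30
    min_kept_length: int = 0

    def __post_init__(self):
        for name in ("seed_mismatches", "min_match_score",
                     "min_palindrome_score", "min_kept_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AdaptorSet:
    name: str
    sequences: Tuple[Tuple[str, str], ...]  # (label, sequence)

    def __post_init__(self):
        if self.name == "None" and self.sequences:
            raise ValueError("the 'None' adaptor set must be empty")
        for label, seq in self.sequences:
            if len(seq) < MIN_ADAPTOR_LEN:
                raise ValueError(
                    f"adaptor {label!r} shorter than {MIN_ADAPTOR_LEN} nt"
                )

    def __bool__(self) -> bool:
        return bool(self.sequences)

    @property
    def readthrough_candidates(self) -> Tuple[str, ...]:
        """Sequences an overhang may be compared against in palindrome mode.

        Includes every adaptor as given plus the reverse complement of the
        ligated 'Prefix' adapters (read-through runs into the opposing
        adaptor's reverse complement).
        """
        cands = [seq for _, seq in self.sequences]
        for label, seq in self.sequences:
            if "Prefix" in label:
                cands.append(reverse_complement(seq))
        # dedupe, order-preserving
        return tuple(dict.fromkeys(cands))

    @classmethod
    def load(cls, name_or_path: Union[str, Path]) -> "AdaptorSet":
        """Resolve a built-in set name, "None", or a user FASTA path."""
        name = str(name_or_path)
        if name == "None":
            return cls("None", ())
        if name in _BUILTIN_FILES:
            ref = resources.files("autoshi").joinpath(
                "adaptors", _BUILTIN_FILES[name]
            )
            with resources.as_file(ref) as path:
                return cls._from_fasta(path, name)
        path = Path(name_or_path)
        if not path.exists():
            raise FileNotFoundError(
                f"unknown adaptor set {name!r}: not a built-in "
                f"{BUILTIN_NAMES} and no such file"
            )
        return cls._from_fasta(path, path.stem)

    @classmethod
    def _from_fasta(cls, path: Path, name: str) -> "AdaptorSet":
        seqs = tuple(
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        )
        if not seqs:
            raise ValueError(f"adaptor FASTA {path} contains no sequences")
        return cls(name, seqs)


NONE_SET = AdaptorSet("None", ())


@lru_cache(maxsize=16)
def _load_builtin(name: str) -> AdaptorSet:
    return AdaptorSet.load(name)


def builtin_sets() -> List[AdaptorSet]:
    return [_load_builtin(n) for n in BUILTIN_NAMES]


def _best_clip_position(codes: np.ndarray, aset: AdaptorSet,
                        params: ClipParams) -> Optional[int]:
    """Best qualifying truncation point over all adaptors, or None."""
    best: Optional[Tuple[int, int]] = None  # (score, pos)
    for _, adaptor in aset.sequences:
        score, seed_mm, _ = semi_global_scores(codes, encode(adaptor))
        ok = (score >= params.min_match_score) & \
             (seed_mm <= params.seed_mismatches)
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        p = int(idx[np.argmax(score[idx])])  # ties -> leftmost placement
        s = int(score[p])
        if best is None or s > best[0] or (s == best[0] and p < best[1]):
            best = (s, p)
    return None if best is None else best[1]


def clip_read(read: Read, aset: AdaptorSet, params: ClipParams = ClipParams()) -> Read:
    """Remove a 3' adaptor by truncation; the read is never otherwise edited.

    The adaptor may overhang the read end (partial trailing adaptors are
    found); a placement qualifies when its match score reaches
    ``min_match_score`` with at most ``seed_mismatches`` errors in the 8-nt
    seed.  An unmatched read is returned unchanged; an empty result is
    allowed (callers length-filter).
    """
    if not aset or len(read) == 0:
        return read
    pos = _best_clip_position(encode(read.seq), aset, params)
    return read if pos is None else read.cut(0, pos)


def _palindrome_candidate(r1_codes: np.ndarray, rc2_codes: np.ndarray,
                          min_score: int) -> Optional[Tuple[int, int]]:
    """Best read-through geometry: insert length L aligning r1[:L] with the
    last L bases of revcomp(r2).  Returns (L, score) or None."""
    n1, n2 = len(r1_codes), len(rc2_codes)
    vmax = min(n1, n2)
    if vmax == 0:
        return None
    m = outie_matches(r1_codes, rc2_codes)
    vs = np.arange(1, vmax + 1)
    scores = 2 * m[1:] - vs
    best = int(np.argmax(scores))
    if scores[best] < min_score:
        return None
    return int(vs[best]), int(scores[best])


def _overhang_is_adaptor(overhang: str, candidates: Sequence[str],
                         max_mismatch_frac: float = 0.25,
                         min_check: int = 6) -> bool:
    for cand in candidates:
        k = min(len(overhang), len(cand))
        if k < min_check:
            continue
        mm = sum(a != b for a, b in zip(overhang[:k], cand[:k]))
        if mm <= max_mismatch_frac * k:
            return True
    return False


def clip_pair_palindrome(r1: Read, r2: Read, aset: AdaptorSet,
                         params: ClipParams = ClipParams(),
                         _geom: Optional[Tuple[int, int]] = None
                         ) -> Tuple[Read, Read]:
    """Remove read-through adaptors from a mate pair.

    If read 1 and the reverse complement of read 2 overlap with score >=
    ``min_palindrome_score`` and the implied insert is shorter than the
    reads, each mate whose overhanging bases match an adaptor from the set
    is truncated to the insert length.  The per-mate check anchors the
    truncation on the set's own adapters, which is what lets closely
    related adaptor families be told apart.  Mates without a confirmed
    overhang fall back to per-read :func:`clip_read`.
    """
    if not aset:
        return r1, r2
    cand = _geom
    if cand is None and len(r1) and len(r2):
        cand = _palindrome_candidate(
            encode(r1.seq), encode(reverse_complement(r2.seq)),
            params.min_palindrome_score,
        )
    if cand is not None:
        insert, _ = cand
        if insert < max(len(r1), len(r2)):
            rt = aset.readthrough_candidates
            ok1 = _overhang_is_adaptor(r1.seq[insert:], rt)
            ok2 = _overhang_is_adaptor(r2.seq[insert:], rt)
            if ok1 or ok2:
                out1 = r1.cut(0, insert) if ok1 else clip_read(r1, aset, params)
                out2 = r2.cut(0, insert) if ok2 else clip_read(r2, aset, params)
                return out1, out2
    return clip_read(r1, aset, params), clip_read(r2, aset, params)


PairOrRead = Union[Read, Tuple[Read, Read]]


def detect_adaptor_set(sample_reads: Sequence[PairOrRead],
                       candidates: Optional[Sequence[AdaptorSet]] = None,
                       paired: bool = False,
                       params: ClipParams = ClipParams(),
                       min_gain: float = DEFAULT_MIN_GAIN) -> str:
    """Pick the adaptor set that leaves the fewest retained bases.

    Each candidate set clips the subsample once (palindrome mode for pairs);
    the set retaining the minimum number of bases wins, with ties broken
    toward the lexicographically first name.  If the winner removes less
    than ``min_gain`` of all bases the data are declared adaptor-free and
    "None" is returned.
    """
    if not sample_reads:
        raise ValueError("cannot detect adaptors on an empty subsample")
    if candidates is None:
        candidates = builtin_sets()

    if paired:
        pairs: List[Tuple[Read, Read]] = list(sample_reads)  # type: ignore
        total = sum(len(a) + len(b) for a, b in pairs)
        # The overlap geometry is set-independent; compute it once per pair.
        geoms = []
        for a, b in pairs:
            g = None
            if len(a) and len(b):
                g = _palindrome_candidate(
                    encode(a.seq), encode(reverse_complement(b.seq)),
                    params.min_palindrome_score,
                )
            geoms.append(g)
    else:
        reads: List[Read] = list(sample_reads)  # type: ignore
        total = sum(len(r) for r in reads)
    if total == 0:
        raise ValueError("cannot detect adaptors: subsample has no bases")

    retained = {}
    for aset in candidates:
        if not aset:
            retained[aset.name] = total
            continue
        kept = 0
        if paired:
            for (a, b), g in zip(pairs, geoms):
                if g is None:  # no overlap: palindrome step cannot apply
                    ca, cb = (clip_read(a, aset, params),
                              clip_read(b, aset, params))
                else:
                    ca, cb = clip_pair_palindrome(a, b, aset, params, _geom=g)
                kept += len(ca) + len(cb)
        else:
            for r in reads:
                kept += len(clip_read(r, aset, params))
        retained[aset.name] = kept

    best_name = min(retained, key=lambda n: (retained[n], n))
    if (total - retained[best_name]) < min_gain * total:
        return "None"
    return best_name
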