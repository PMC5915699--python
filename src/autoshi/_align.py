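"""Vectorised ungapped alignment kernels shared by clipping and stitching."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_BASES = (65, 67, 71, 84)  # ASCII A, C, G, T


def encode(seq: str) -> np.ndarray:
    """Sequence as uint8 ASCII codes; non-ACGT codes never match anything."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def match_counts_all_lags(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact-match counts between ``a`` and ``b`` at every relative shift.

    Returns an array ``m`` of length ``len(a) + len(b) - 1`` where
    ``m[len(a) + len(b) - 1 - v]`` counts matches between the length-``v``
    suffix of ``a`` and the length-``v`` prefix of ``b`` (the "innie"
    geometry), and ``m[v - 1]`` counts matches between the length-``v``
    prefix of ``a`` and the length-``v`` suffix of ``b`` ("outie").
    """
    out = np.zeros(len(a) + len(b) - 1, dtype=np.int64)
    for base in _BASES:
        ia = (a == base).astype(np.int64)
        ib = (b == base).astype(np.int64)
        out += np.convolve(ia, ib[::-1])
    return out


def innie_matches(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """``res[v]`` = matches between a-suffix and b-prefix of length v.

    Valid for v in [1, min(len(a), len(b))]; index 0 is unused.
    """
    m = match_counts_all_lags(a, b)
    n1, n2 = len(a), len(b)
    vmax = min(n1, n2)
    res = np.zeros(vmax + 1, dtype=np.int64)
    vs = np.arange(1, vmax + 1)
    res[1:] = m[n1 + n2 - 1 - vs]
    return res


def outie_matches(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """``res[v]`` = matches between a-prefix and b-suffix of length v."""
    m = match_counts_all_lags(a, b)
    vmax = min(len(a), len(b))
    res = np.zeros(vmax + 1, dtype=np.int64)
    vs = np.arange(1, vmax + 1)
    res[1:] = m[vs - 1]
    return res


def semi_global_scores(read: np.ndarray, probe: np.ndarray, seed_len: int = 8):
    """Score every placement of ``probe`` against ``read`` starting at p.

    The probe may overhang the 3' end of the read; overhanging positions are
    simply not compared.  Returns (score, seed_mismatches, aligned_len)
    arrays indexed by start position p, with score = matches - mismatches
    over the aligned region.
    """
    n, m = len(read), len(probe)
    if n == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z
    padded = np.zeros(n + m - 1, dtype=np.uint8)  # pad value 0 matches nothing
    padded[:n] = read
    win = sliding_window_view(padded, m)[:n]
    valid = win != 0
    eq = win == probe
    aligned = valid.sum(axis=1)
    matches = (eq & valid).sum(axis=1)
    score = 2 * matches - aligned
    seed_mm = (~eq & valid)[:, :seed_len].sum(axis=1)
    return score, seed_mm, aligned
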