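"""Smith-Waterman local alignment with the pipeline's scoring conventions.

Scoring is +M for a match, -MM for a mismatch, -IN per inserted or
deleted base (linear gaps).  An N base never counts as a match — even
against another N — reflecting that an unknown base call carries no
evidence of identity.  Kernels are numba-compiled and operate on uint8
base codes (A=0..N=4); thin wrappers accept plain strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._encode import seq_to_codes

_N_CODE = 4


@njit(cache=True, nogil=True)
def _sw_score(a, b, M, MM, IN):  # pragma: no cover - numba kernel
    la, lb = a.shape[0], b.shape[0]
    prev = np.zeros(lb + 1, dtype=np.int64)
    cur = np.zeros(lb + 1, dtype=np.int64)
    best = 0
    for i in range(1, la + 1):
        cur[0] = 0
        ai = a[i - 1]
        for j in range(1, lb + 1):
            if ai == b[j - 1] and ai != _N_CODE:
                s = prev[j - 1] + M
            else:
                s = prev[j - 1] - MM
            if prev[j] - IN > s:
                s = prev[j] - IN
            if cur[j - 1] - IN > s:
                s = cur[j - 1] - IN
            if s < 0:
                s = 0
            cur[j] = s
            if s > best:
                best = s
        prev, cur = cur, prev
    return best


@njit(cache=True, nogil=True)
def _sw_align(a, b, M, MM, IN):  # pragma: no cover - numba kernel
    """Full DP with traceback.

    Returns (score, matches, mismatches, gaps, a_start, a_end, b_start,
    b_end) for one best-scoring local alignment; coordinates are 0-based
    half-open on the inputs.  Ties are broken deterministically: the
    traceback prefers diagonal over up over left, and the end cell is
    the first maximum in row-major order.
    """
    la, lb = a.shape[0], b.shape[0]
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            if ai == b[j - 1] and ai != _N_CODE:
                s = H[i - 1, j - 1] + M
            else:
                s = H[i - 1, j - 1] - MM
            if H[i - 1, j] - IN > s:
                s = H[i - 1, j] - IN
            if H[i, j - 1] - IN > s:
                s = H[i, j - 1] - IN
            if s < 0:
                s = 0
            H[i, j] = s
            if s > best:
                best = s
                bi = i
                bj = j
    matches = 0
    mismatches = 0
    gaps = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0:
        here = H[i, j]
        if a[i - 1] == b[j - 1] and a[i - 1] != _N_CODE:
            diag = H[i - 1, j - 1] + M
            is_match = True
        else:
            diag = H[i - 1, j - 1] - MM
            is_match = False
        if here == diag:
            if is_match:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif here == H[i - 1, j] - IN:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    return best, matches, mismatches, gaps, i, bi, j, bj


@njit(cache=True, nogil=True)
def _pair_threshold(lo, hi, M, MM, IN, cutoff):  # pragma: no cover - numba kernel
    if hi * cutoff > lo:
        return hi * float(M)
    return (M * 4.0 / 5.0 - MM * 2.0 / 50.0 - IN * 2.0 / 10.0) * hi


@njit(cache=True, nogil=True)
def _scores_vs_many(q, mat, lens, M, MM, IN, cutoff):  # pragma: no cover - numba kernel
    """Best local score of query q against each row of a padded matrix.

    Rows whose similarity threshold T is provably unreachable (the best
    local score is capped at M * min_len) get -1 without alignment;
    -1 never exceeds any threshold, so pruning cannot change decisions.
    """
    n = lens.shape[0]
    qlen = q.shape[0]
    out = np.full(n, -1, dtype=np.int64)
    for r in range(n):
        lo = qlen if qlen < lens[r] else lens[r]
        hi = qlen if qlen > lens[r] else lens[r]
        if M * lo <= _pair_threshold(lo, hi, M, MM, IN, cutoff):
            continue
        out[r] = _sw_score(q, mat[r, : lens[r]], M, MM, IN)
    return out


@njit(cache=True, nogil=True)
def _first_similar(
    q, qlen, mat, lens, n, M, MM, IN, cutoff
):  # pragma: no cover - numba kernel
    """Index of the first row similar to q under the two-branch threshold.

    Rows whose threshold T is unreachable given the length pair (best
    local score <= M * min_len) are skipped without alignment.
    Returns -1 when no row is similar.
    """
    for r in range(n):
        lo = qlen if qlen < lens[r] else lens[r]
        hi = qlen if qlen > lens[r] else lens[r]
        T = _pair_threshold(lo, hi, M, MM, IN, cutoff)
        if M * lo <= T:
            continue
        score = _sw_score(q, mat[r, : lens[r]], M, MM, IN)
        if score > T:
            return r
    return -1


@dataclass(frozen=True)
class AlignmentStats:
    """One best local alignment: score plus aligned-column composition."""

    score: int
    matches: int
    mismatches: int
    gaps: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def identity(self) -> float:
        """Matched bases over all aligned columns (matches+mismatches+gaps)."""
        denom = self.matches + self.mismatches + self.gaps
        return self.matches / denom if denom else 0.0


def _check_pair(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    return seq_to_codes(a), seq_to_codes(b)


def sw_score(a: str, b: str, M: int = 2, MM: int = 2, IN: int = 3) -> int:
    """Best Smith-Waterman local score of two sequences (never negative)."""
    ca, cb = _check_pair(a, b)
    return int(_sw_score(ca, cb, M, MM, IN))


def sw_align(a: str, b: str, M: int = 2, MM: int = 2, IN: int = 3) -> AlignmentStats:
    """Best local alignment of two sequences with traceback statistics."""
    ca, cb = _check_pair(a, b)
    return AlignmentStats(*map(int, _sw_align(ca, cb, M, MM, IN)))


class PaddedSeqs:
    """Row-padded uint8 matrix over a set of sequences, for batch kernels.

    Supports amortised O(1) appends (capacity doubling in both
    dimensions) so greedy clustering loops can grow the target set
    without re-packing it.
    """

    def __init__(self, seqs: list[str] = ()):  # type: ignore[assignment]
        n = len(seqs)
        self._n = n
        self._lens = np.zeros(max(n, 8), dtype=np.int64)
        self._lens[:n] = [len(s) for s in seqs]
        width = int(self._lens[:n].max()) if n else 8
        self._mat = np.zeros((max(n, 8), width), dtype=np.uint8)
        for r, s in enumerate(seqs):
            self._mat[r, : len(s)] = seq_to_codes(s)

    def append(self, seq: str) -> None:
        rows, width = self._mat.shape
        if self._n == rows or len(seq) > width:
            new = np.zeros(
                (max(rows * 2, self._n + 1), max(width * 2, len(seq))), dtype=np.uint8
            )
            new[:rows, :width] = self._mat
            self._mat = new
            self._lens = np.resize(self._lens, self._mat.shape[0])
            self._lens[self._n :] = 0
        self._mat[self._n, : len(seq)] = seq_to_codes(seq)
        self._lens[self._n] = len(seq)
        self._n += 1

    @property
    def mat(self) -> np.ndarray:
        return self._mat[: self._n]

    @property
    def lens(self) -> np.ndarray:
        return self._lens[: self._n]

    def __len__(self) -> int:
        return self._n
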