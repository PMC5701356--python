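"""Integer encoding of DNA k-mers over the 5-letter alphabet {A,C,G,T,N}.

Each k-mer is packed into a single unsigned 64-bit integer in base 5
(A=0, C=1, G=2, T=3, N=4), which is injective for k <= 27 since
5**27 < 2**64.  The packed representation lets the counting and
signature stages run as vectorised numpy operations instead of Python
dictionaries, which matters at amplicon-run scale (10^7-10^8 windows).
"""

from __future__ import annotations

import numpy as np

#: Longest k-mer representable as a base-5 uint64 code.
MAX_PACKED_K = 27

BASES = "ACGTN"

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(BASES):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def encode_kmer(kmer: str) -> int:
    """Pack one k-mer string into its base-5 integer code."""
    if len(kmer) > MAX_PACKED_K:
        raise ValueError(f"k-mer longer than {MAX_PACKED_K} cannot be packed")
    code = 0
    for ch in kmer.upper():
        idx = BASES.find(ch)
        if idx < 0:
            raise ValueError(f"invalid base {ch!r} in k-mer")
        code = code * 5 + idx
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a k-mer of known length."""
    out = []
    for _ in range(k):
        code, rem = divmod(code, 5)
        out.append(BASES[rem])
    return "".join(reversed(out))


def decode_codes(codes: np.ndarray, k: int) -> list[str]:
    """Decode an array of packed codes back to k-mer strings."""
    return [decode_kmer(int(c), k) for c in codes]


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a DNA string to a uint8 array of base codes 0..4.

    Raises ValueError if the sequence contains a character outside
    {A,C,G,T,N} (case-insensitive).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == 255).any():
        bad = chr(int(raw[codes == 255][0]))
        raise ValueError(f"invalid base {bad!r} in sequence")
    return codes


def window_codes(
    reads: list[str], k: int, with_positions: bool = False
) -> tuple[np.ndarray, ...]:
    """Packed codes of every sliding-window k-mer of every read.

    Returns ``(codes,)`` or, when *with_positions* is true,
    ``(codes, read_id, pos)`` where ``pos`` is the 0-based start of each
    window inside its read.  Windows are emitted in read order then
    position order, exactly matching the sliding-window enumeration.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_PACKED_K:
        raise ValueError(f"packed window codes require k <= {MAX_PACKED_K}")
    if not reads:
        empty = np.empty(0, dtype=np.uint64)
        if with_positions:
            return empty, np.empty(0, np.int64), np.empty(0, np.int64)
        return (empty,)

    concat = "".join(reads)
    base = _LUT[np.frombuffer(concat.encode("ascii"), dtype=np.uint8)]
    if (base == 255).any():
        raise ValueError("invalid base in reads; filter inputs first")

    lengths = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    n_win = np.maximum(lengths - k + 1, 0)
    total = int(n_win.sum())
    if total == 0:
        empty = np.empty(0, dtype=np.uint64)
        if with_positions:
            return empty, np.empty(0, np.int64), np.empty(0, np.int64)
        return (empty,)

    # 0-based start position of each valid window within its read
    win_read = np.repeat(np.arange(len(reads), dtype=np.int64), n_win)
    first_idx = np.concatenate(([0], np.cumsum(n_win)))[:-1]
    pos = np.arange(total, dtype=np.int64) - np.repeat(first_idx, n_win)
    start = np.repeat(offsets[:-1], n_win) + pos

    # Horner evaluation of the base-5 code, k vectorised passes
    m = len(base) - k + 1
    acc = base[:m].astype(np.uint64)
    for j in range(1, k):
        acc *= np.uint64(5)
        acc += base[j : j + m]
    codes = acc[start]

    if with_positions:
        return codes, win_read, pos
    return (codes,)
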