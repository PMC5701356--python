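"""Step 2 — read signatures and within-sample similarity correction.

A read's *signature* is the part of it covered by significant k-mers:
the union of the position intervals of every significant k-mer found in
the read, with the maximal contiguous covered segments concatenated in
read order.  For a tumour read this isolates the clone-specific VDJ
junction; reads with no significant k-mer (polyclonal background) yield
an empty signature and are dropped.

Within one sample, signatures differing only by sequencing noise are
merged: two signatures are *similar* when their Smith-Waterman score
strictly exceeds a length-dependent threshold T,

    T = max(l1, l2) * M                                  if 0.7*max > min
    T = (M*4/5 - MM*2/50 - IN*2/10) * max(l1, l2)        otherwise

With the default M = MM = 2, IN = 3 the second branch's coefficient is
0.92.  The first branch makes pairs whose shorter member is below 70%
of the longer unreachable (T is the maximum attainable score), so such
pairs are never merged.  Correction repeatedly absorbs the
lower-frequency member of a similar pair into the higher-frequency one,
summing frequencies, until no similar pair remains.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import align
from ._encode import seq_to_codes, window_codes
from .align import PaddedSeqs, _first_similar, _sw_score
from .kmer import SignificantKmerSet

__all__ = [
    "ScoringParams",
    "Signature",
    "SignatureSet",
    "build_signature",
    "collect_signatures",
    "sw_score",
    "similarity_threshold",
    "are_similar",
    "correct_signatures",
]


@dataclass(frozen=True)
class ScoringParams:
    """Smith-Waterman scoring constants and the 70% length-ratio cutoff."""

    match: int = 2
    mismatch: int = 2
    indel: int = 3
    length_ratio_cutoff: float = 0.7

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be > 0")
        if self.mismatch < 0 or self.indel < 0:
            raise ValueError("mismatch/indel penalties must be >= 0")
        if not 0 < self.length_ratio_cutoff < 1:
            raise ValueError("length_ratio_cutoff must be in (0, 1)")


@dataclass
class Signature:
    """A signature sequence with its read support in one sample."""

    sequence: str
    frequency: int = 1
    exemplar_read: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("signature sequence must be non-empty")
        if self.frequency < 1:
            raise ValueError("signature frequency must be >= 1")


@dataclass
class SignatureSet:
    """The signature collection Gamma_i of one sample."""

    sample_index: int = 0
    signatures: list[Signature] = field(default_factory=list)
    n_empty_reads: int = 0

    def total_frequency(self) -> int:
        return sum(s.frequency for s in self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_index={self.sample_index}\tn_empty_reads={self.n_empty_reads}\n")
            fh.write("#sequence\tfrequency\texemplar_read\n")
            for s in self.signatures:
                fh.write(f"{s.sequence}\t{s.frequency}\t{s.exemplar_read}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureSet":
        out = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line[1:].split("\t"):
                        key, _, val = tok.partition("=")
                        if key == "sample_index":
                            out.sample_index = int(val)
                        elif key == "n_empty_reads":
                            out.n_empty_reads = int(val)
                    continue
                if line:
                    seq, freq, exemplar = (line.split("\t") + [""])[:3]
                    out.signatures.append(Signature(seq, int(freq), exemplar))
        return out


def _segments_from_positions(positions: Iterable[int], k: int) -> list[tuple[int, int]]:
    """Union the half-open intervals [p, p+k) of sorted 0-based starts."""
    segments: list[tuple[int, int]] = []
    start = end = None
    for p in positions:
        if start is None:
            start, end = p, p + k
        elif p <= end:
            end = p + k
        else:
            segments.append((start, end))
            start, end = p, p + k
    if start is not None:
        segments.append((start, end))
    return segments


def build_signature(read: str, psi: SignificantKmerSet, k: int | None = None) -> str:
    """Signature of one read: concatenated maximal segments covered by Psi.

    Returns the empty string when no k-mer of the read is significant.
    """
    if k is None:
        k = psi.k
    elif k != psi.k:
        raise ValueError(f"k={k} does not match the significant set's k={psi.k}")
    read = read.upper()
    hits = [p for p in range(len(read) - k + 1) if read[p : p + k] in psi.kmers]
    return "".join(read[s:e] for s, e in _segments_from_positions(hits, k))


def collect_signatures(
    reads: Iterable[str],
    psi: SignificantKmerSet,
    k: int | None = None,
    sample_index: int = 0,
) -> SignatureSet:
    """Pool identical signatures over a sample's reads.

    Frequency of a signature = number of reads producing it; the first
    read encountered is kept as the exemplar.  Reads with an empty
    signature are counted in ``n_empty_reads`` and excluded.  Uses a
    vectorised membership scan over packed window codes; the output is
    identical to calling :func:`build_signature` read by read.
    """
    if k is None:
        k = psi.k
    elif k != psi.k:
        raise ValueError(f"k={k} does not match the significant set's k={psi.k}")
    read_list = [r.upper() for r in reads]
    pooled: dict[str, Signature] = {}
    n_empty = 0
    if not read_list:
        return SignatureSet(sample_index=sample_index)

    psi_codes = psi.codes()
    if psi_codes.shape[0] == 0:
        return SignatureSet(sample_index=sample_index, n_empty_reads=len(read_list))

    codes, read_id, pos = window_codes(read_list, k, with_positions=True)
    if codes.shape[0]:
        idx = np.searchsorted(psi_codes, codes)
        idx[idx == psi_codes.shape[0]] = 0
        member = psi_codes[idx] == codes
        hit_read = read_id[member]
        hit_pos = pos[member]
    else:
        hit_read = np.empty(0, np.int64)
        hit_pos = np.empty(0, np.int64)

    # group hit positions by read; window order is already (read, pos)
    boundaries = np.flatnonzero(np.diff(hit_read)) + 1
    groups = np.split(hit_pos, boundaries)
    reads_with_hits = hit_read[np.concatenate(([0], boundaries))] if hit_read.size else []

    n_empty = len(read_list) - len(groups) if hit_read.size else len(read_list)
    for rid, positions in zip(reads_with_hits, groups):
        read = read_list[rid]
        sig = "".join(
            read[s:e] for s, e in _segments_from_positions(positions.tolist(), k)
        )
        entry = pooled.get(sig)
        if entry is None:
            pooled[sig] = Signature(sig, 1, read)
        else:
            entry.frequency += 1
    return SignatureSet(
        sample_index=sample_index,
        signatures=list(pooled.values()),
        n_empty_reads=n_empty,
    )


def sw_score(a: str, b: str, params: ScoringParams = ScoringParams()) -> int:
    """Smith-Waterman best local score under the run's scoring constants."""
    return align.sw_score(a, b, params.match, params.mismatch, params.indel)


def similarity_threshold(
    len_a: int, len_b: int, params: ScoringParams = ScoringParams()
) -> float:
    """The length-dependent similarity threshold T (see module docstring)."""
    if len_a < 1 or len_b < 1:
        raise ValueError("lengths must be >= 1")
    lo, hi = min(len_a, len_b), max(len_a, len_b)
    if hi * params.length_ratio_cutoff > lo:
        return float(hi * params.match)
    coeff = (
        params.match * 4 / 5
        - params.mismatch * 2 / 50
        - params.indel * 2 / 10
    )
    return coeff * hi


def _sequence_of(x) -> str:
    return x.sequence if hasattr(x, "sequence") else x


def are_similar(a, b, params: ScoringParams = ScoringParams()) -> bool:
    """True iff the local-alignment score strictly exceeds the threshold T.

    Accepts :class:`Signature` objects or plain sequences.
    """
    sa, sb = _sequence_of(a), _sequence_of(b)
    lo, hi = sorted((len(sa), len(sb)))
    T = similarity_threshold(len(sa), len(sb), params)
    if hi * params.length_ratio_cutoff > lo:
        # T equals the full-length score of the longer sequence, while the
        # best local score is capped at match * lo < T: never similar.
        return False
    return sw_score(sa, sb, params) > T


def _rank_key(sig: Signature):
    # higher frequency first; lexicographically smaller sequence absorbs on ties
    return (-sig.frequency, sig.sequence)


def correct_signatures(
    sset: SignatureSet, params: ScoringParams = ScoringParams()
) -> SignatureSet:
    """Merge similar signatures until none remain (fixed point).

    Signatures are ranked by descending frequency (ties: lexicographic);
    each is absorbed into the first higher-ranked similar survivor, so
    dominant clones act as attractors for their error halo.  Total
    frequency is conserved; passes repeat until no merge occurs.
    """
    entries = [replace(s) for s in sset.signatures]
    changed = True
    while changed:
        changed = False
        entries.sort(key=_rank_key)
        survivors: list[Signature] = []
        pack = PaddedSeqs()
        for sig in entries:
            merged = False
            if survivors:
                r = int(
                    _first_similar(
                        seq_to_codes(sig.sequence),
                        len(sig.sequence),
                        pack.mat,
                        pack.lens,
                        len(survivors),
                        params.match,
                        params.mismatch,
                        params.indel,
                        params.length_ratio_cutoff,
                    )
                )
                if r >= 0:
                    survivors[r].frequency += sig.frequency
                    merged = True
                    changed = True
            if not merged:
                survivors.append(sig)
                pack.append(sig.sequence)
        entries = survivors
    entries.sort(key=_rank_key)
    return SignatureSet(
        sample_index=sset.sample_index,
        signatures=entries,
        n_empty_reads=sset.n_empty_reads,
    )
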