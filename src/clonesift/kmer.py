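"""Step 1 — k-mer counting across samples and significant-k-mer selection.

Every read of every sample is decomposed into sliding-window k-mers; the
per-sample occurrence counts form a frequency table C mapping each k-mer
to an n-sample count vector.  A k-mer is *significant* when its counts
differ by at least tau orders of magnitude between some pair of samples:

    exists i != j with
        |log10 C[i] - log10 C[j]| >= tau      (both counts nonzero)
        log10 C[j] >= tau                      (C[i] = 0, C[j] != 0)
        log10 C[i] >= tau                      (C[j] = 0, C[i] != 0)

Because a tumour clone is heavily enriched in the diagnostic sample and
diluted (or absent) in follow-ups, its junction-spanning k-mers trip this
criterion while germline-segment k-mers, shared by the polyclonal
background at comparable rates everywhere, do not.

Counting semantics: a k-mer occurring twice inside one read contributes
two occurrences.  This makes the per-sample totals obey the conservation
law sum_kmers C[i] = sum_reads max(len - k + 1, 0), which the tests rely
on.  N base calls are kept verbatim as a fifth letter so that degraded
reads still contribute countable k-mers.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._encode import (
    MAX_PACKED_K,
    decode_codes,
    encode_kmer,
    window_codes,
)

__all__ = [
    "KmerFrequencyTable",
    "SignificantKmerSet",
    "extract_kmers",
    "count_sample_kmers",
    "merge_counts",
    "is_significant",
    "significant_kmers",
    "find_significant_kmers",
]


def extract_kmers(read: str, k: int) -> list[tuple[str, int]]:
    """All sliding-window k-mers of *read* with their 1-based start positions.

    A read shorter than k yields no k-mers; duplicates are kept.

    >>> extract_kmers("ATCCCGTC", 3)[:3]
    [('ATC', 1), ('TCC', 2), ('CCC', 3)]
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    read = read.upper()
    return [(read[p : p + k], p + 1) for p in range(len(read) - k + 1)]


def count_sample_kmers(reads: Iterable[str], k: int) -> dict[str, int]:
    """Occurrence count of every k-mer across all reads of one sample."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    counts: Counter[str] = Counter()
    for read in reads:
        read = read.upper()
        counts.update(read[p : p + k] for p in range(len(read) - k + 1))
    return dict(counts)


class KmerFrequencyTable(Mapping):
    """Map from k-mer to its per-sample occurrence-count vector (the function C).

    Backed by a sorted array of packed base-5 codes plus an (m, n) count
    matrix, so million-key tables stay compact.  The mapping interface
    (iteration, membership, item access by k-mer string) is provided for
    convenience at inspection scale.
    """

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray):
        if counts.ndim != 2 or counts.shape[0] != codes.shape[0]:
            raise ValueError("counts must be an (n_kmers, n_samples) matrix")
        if counts.shape[1] < 1:
            raise ValueError("need at least one sample")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        order = np.argsort(codes)
        self.k = int(k)
        self._codes = codes[order]
        self._counts = np.asarray(counts)[order]

    # -- construction -------------------------------------------------

    @classmethod
    def from_sample_counts(
        cls, per_sample_counts: Sequence[Mapping[str, int]], k: int | None = None
    ) -> "KmerFrequencyTable":
        """Merge per-sample count maps into one table (absences become 0)."""
        if len(per_sample_counts) < 1:
            raise ValueError("need at least one sample")
        ks = {len(key) for m in per_sample_counts for key in m}
        if len(ks) > 1:
            raise ValueError(f"mismatched k-mer lengths across samples: {sorted(ks)}")
        if ks:
            inferred = ks.pop()
            if k is not None and k != inferred:
                raise ValueError(f"k={k} does not match key length {inferred}")
            k = inferred
        elif k is None:
            raise ValueError("cannot infer k from empty count maps; pass k=")

        n = len(per_sample_counts)
        keys = sorted({key for m in per_sample_counts for key in m})
        codes = np.array([encode_kmer(key) for key in keys], dtype=np.uint64)
        counts = np.zeros((len(keys), n), dtype=np.int64)
        index = {key: i for i, key in enumerate(keys)}
        for j, m in enumerate(per_sample_counts):
            for key, c in m.items():
                counts[index[key], j] = c
        return cls(k, codes, counts)

    @classmethod
    def from_reads(
        cls, samples: Sequence[Sequence[str]], k: int
    ) -> "KmerFrequencyTable":
        """Count all samples directly from reads (vectorised fast path)."""
        if k < 1:
            raise ValueError("k must be a positive integer")
        if len(samples) < 1:
            raise ValueError("need at least one sample")
        if k > MAX_PACKED_K:
            maps = [count_sample_kmers(reads, k) for reads in samples]
            return cls.from_sample_counts(maps, k=k)
        uniq, cnts = [], []
        for reads in samples:
            (codes,) = window_codes(list(reads), k)
            u, c = np.unique(codes, return_counts=True)
            uniq.append(u)
            cnts.append(c)
        all_codes = np.unique(np.concatenate(uniq)) if uniq else np.empty(0, np.uint64)
        counts = np.zeros((all_codes.shape[0], len(samples)), dtype=np.int64)
        for j, (u, c) in enumerate(zip(uniq, cnts)):
            counts[np.searchsorted(all_codes, u), j] = c
        return cls(k, all_codes, counts)

    # -- mapping interface --------------------------------------------

    def __len__(self) -> int:
        return self._codes.shape[0]

    def __iter__(self):
        for kmer in decode_codes(self._codes, self.k):
            yield kmer

    def __contains__(self, kmer) -> bool:
        try:
            code = np.uint64(encode_kmer(kmer))
        except (ValueError, TypeError):
            return False
        i = np.searchsorted(self._codes, code)
        return i < len(self._codes) and self._codes[i] == code

    def __getitem__(self, kmer: str) -> np.ndarray:
        code = np.uint64(encode_kmer(kmer))
        i = np.searchsorted(self._codes, code)
        if i >= len(self._codes) or self._codes[i] != code:
            raise KeyError(kmer)
        return self._counts[i].copy()

    @property
    def n_samples(self) -> int:
        return self._counts.shape[1]

    @property
    def count_matrix(self) -> np.ndarray:
        """(n_kmers, n_samples) count matrix, rows sorted by packed code."""
        return self._counts

    def sample_totals(self) -> np.ndarray:
        return self._counts.sum(axis=0)

    # -- serialization ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write ``kmer<TAB>c1<TAB>...<TAB>cn`` with one '#' header line."""
        with open(path, "w") as fh:
            labels = "\t".join(f"c{j + 1}" for j in range(self.n_samples))
            fh.write(f"#kmer\t{labels}\n")
            for kmer, row in zip(decode_codes(self._codes, self.k), self._counts):
                fh.write(kmer + "\t" + "\t".join(str(int(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerFrequencyTable":
        keys, rows = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                keys.append(parts[0])
                rows.append([int(x) for x in parts[1:]])
        if not keys:
            raise ValueError(f"no k-mer rows in {path}")
        codes = np.array([encode_kmer(key) for key in keys], dtype=np.uint64)
        return cls(len(keys[0]), codes, np.asarray(rows, dtype=np.int64))


def merge_counts(
    per_sample_counts: Sequence[Mapping[str, int]], k: int | None = None
) -> KmerFrequencyTable:
    """Merge ordered per-sample k-mer count maps into a frequency table."""
    return KmerFrequencyTable.from_sample_counts(per_sample_counts, k=k)


@dataclass(frozen=True)
class SignificantKmerSet:
    """The set Psi of significant k-mers for one multi-sample run."""

    k: int
    tau: float
    kmers: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers

    def __iter__(self):
        return iter(self.kmers)

    def codes(self) -> np.ndarray:
        """Sorted packed codes of the member k-mers (for vectorised lookup)."""
        return np.sort(
            np.array([encode_kmer(km) for km in self.kmers], dtype=np.uint64)
        )

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\ttau={self.tau}\n")
            for km in sorted(self.kmers):
                fh.write(km + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SignificantKmerSet":
        k = tau = None
        kmers = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line[1:].split("\t"):
                        key, _, val = tok.partition("=")
                        if key == "k":
                            k = int(val)
                        elif key == "tau":
                            tau = float(val)
                elif line:
                    kmers.append(line)
        if k is None or tau is None:
            raise ValueError(f"missing k/tau header in {path}")
        return cls(k=k, tau=tau, kmers=frozenset(kmers))


def is_significant(freq_vector: Sequence[int], tau: float) -> bool:
    """Evaluate the three-case order-of-magnitude criterion for one k-mer.

    True iff some ordered pair of samples (i, j), i != j, satisfies one
    of the three cases above.  With a single sample no pair exists and
    the answer is False.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    vec = [int(v) for v in freq_vector]
    if any(v < 0 for v in vec):
        raise ValueError("counts must be non-negative")
    n = len(vec)
    if n < 1:
        raise ValueError("need at least one sample")
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = vec[i], vec[j]
            if ci and cj:
                if abs(math.log10(ci) - math.log10(cj)) >= tau:
                    return True
            elif cj and math.log10(cj) >= tau:
                return True
            elif ci and math.log10(ci) >= tau:
                return True
    return False


def _significant_mask(counts: np.ndarray, tau: float) -> np.ndarray:
    """Vectorised significance decision for every row of a count matrix."""
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.shape[1]
    with np.errstate(divide="ignore"):
        logs = np.log10(np.where(counts > 0, counts, 1.0))
    mask = np.zeros(counts.shape[0], dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = counts[:, i], counts[:, j]
            both = (ci > 0) & (cj > 0)
            mask |= both & (np.abs(logs[:, i] - logs[:, j]) >= tau)
            mask |= (ci == 0) & (cj > 0) & (logs[:, j] >= tau)
            mask |= (cj == 0) & (ci > 0) & (logs[:, i] >= tau)
    return mask


def significant_kmers(table: KmerFrequencyTable, tau: float) -> SignificantKmerSet:
    """Select Psi = { alpha in table : is_significant(C(alpha), tau) }."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if len(table) == 0:
        raise ValueError("k-mer table is empty")
    mask = _significant_mask(table.count_matrix, tau)
    kmers = frozenset(decode_codes(table._codes[mask], table.k))
    return SignificantKmerSet(k=table.k, tau=tau, kmers=kmers)


def find_significant_kmers(
    samples: Sequence[Sequence[str]], k: int, tau: float
) -> SignificantKmerSet:
    """Streaming Psi computation that never materialises the full table.

    Relies on a pruning property of the significance criterion: any
    significant k-mer must reach a count of at least 10**tau in some
    sample (in the both-nonzero case the larger count is >= smaller *
    10**tau >= 10**tau; in the zero cases directly).  Pass one collects
    those candidates per sample; pass two gathers the candidates' full
    count vectors and applies the criterion.  Produces exactly the same
    set as ``significant_kmers(KmerFrequencyTable.from_reads(...), tau)``
    at a fraction of the memory.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k > MAX_PACKED_K:
        return significant_kmers(KmerFrequencyTable.from_reads(samples, k), tau)
    cmin = 10.0**tau * (1.0 - 1e-12)
    candidate_parts = []
    sample_lists = [list(reads) for reads in samples]
    code_cache = []  # one packed-code array per sample, reused in pass two
    for reads in sample_lists:
        (codes,) = window_codes(reads, k)
        code_cache.append(codes)
        u, c = np.unique(codes, return_counts=True)
        candidate_parts.append(u[c >= cmin])
        del u, c
    if not candidate_parts:
        raise ValueError("need at least one sample")
    cand = np.unique(np.concatenate(candidate_parts))
    counts = np.zeros((cand.shape[0], len(sample_lists)), dtype=np.int64)
    if cand.shape[0]:
        for j, codes in enumerate(code_cache):
            idx = np.searchsorted(cand, codes)
            idx[idx == cand.shape[0]] = 0
            hit = cand[idx] == codes
            counts[:, j] = np.bincount(idx[hit], minlength=cand.shape[0])
    mask = _significant_mask(counts, tau)
    return SignificantKmerSet(
        k=k, tau=tau, kmers=frozenset(decode_codes(cand[mask], k))
    )
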