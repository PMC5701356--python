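"""Step 1: k-mer extraction, multi-sample counting, significance selection."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonesift.kmer import (
    KmerFrequencyTable,
    count_sample_kmers,
    extract_kmers,
    find_significant_kmers,
    is_significant,
    merge_counts,
    significant_kmers,
)

# ---------------------------------------------------------------- oracles


def brute_force_significant(vec, tau):
    """Literal evaluation of the three-case criterion over all sample pairs."""
    n = len(vec)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ci, cj = vec[i], vec[j]
            if ci != 0 and cj != 0:
                if abs(math.log10(ci) - math.log10(cj)) >= tau:
                    return True
            elif ci == 0 and cj != 0:
                if math.log10(cj) >= tau:
                    return True
            elif ci != 0 and cj == 0:
                if math.log10(ci) >= tau:
                    return True
    return False


def dict_count(reads, k):
    """Independent per-read enumeration of sliding-window occurrences."""
    out = {}
    for read in reads:
        for p in range(len(read) - k + 1):
            km = read[p : p + k]
            out[km] = out.get(km, 0) + 1
    return out


dna = st.text(alphabet="ACGTN", min_size=0, max_size=40)
reads_strategy = st.lists(dna, min_size=0, max_size=20)


# ---------------------------------------------------------------- extraction


def test_extract_kmers_enumerates_sliding_windows_in_order():
    assert extract_kmers("ATCCCGTC", 3) == [
        ("ATC", 1),
        ("TCC", 2),
        ("CCC", 3),
        ("CCG", 4),
        ("CGT", 5),
        ("GTC", 6),
    ]


@pytest.mark.parametrize(
    "read,k,expected",
    [
        ("AC", 3, []),  # shorter than k
        ("AAAA", 2, [("AA", 1), ("AA", 2), ("AA", 3)]),  # homopolymer duplicates
        ("", 1, []),
        ("acgt", 4, [("ACGT", 1)]),  # case-insensitive
    ],
)
def test_extract_kmers_edge_cases(read, k, expected):
    assert extract_kmers(read, k) == expected


@pytest.mark.parametrize("k", [0, -3])
def test_extract_kmers_rejects_nonpositive_k(k):
    with pytest.raises(ValueError):
        extract_kmers("ACGT", k)
    with pytest.raises(ValueError):
        count_sample_kmers(["ACGT"], k)


# ---------------------------------------------------------------- counting


@pytest.mark.parametrize(
    "reads,k,expected",
    [
        (["ATCCCGTC"], 3, {"ATC": 1, "TCC": 1, "CCC": 1, "CCG": 1, "CGT": 1, "GTC": 1}),
        ([], 3, {}),
        (["AAAA", "AAA"], 3, {"AAA": 3}),  # occurrences, not reads-containing
    ],
)
def test_count_sample_kmers(reads, k, expected):
    assert count_sample_kmers(reads, k) == expected


def test_merge_counts_encodes_absence_as_zero():
    table = merge_counts([{"ATC": 3}, {}], k=3)
    assert table["ATC"].tolist() == [3, 0]
    assert table.n_samples == 2


def test_merge_counts_single_sample_is_identity():
    counts = count_sample_kmers(["ATCCCGTC"], 3)
    table = merge_counts([counts])
    assert {km: int(table[km][0]) for km in table} == counts


def test_merge_counts_example_across_samples():
    maps = [count_sample_kmers(["ATCCCGTC"], 3), count_sample_kmers(["ATCATC"], 3)]
    table = merge_counts(maps)
    assert table["ATC"].tolist() == [1, 2]


def test_merge_counts_rejects_mismatched_k():
    with pytest.raises(ValueError, match="mismatched"):
        merge_counts([{"ATC": 1}, {"AT": 1}])


@settings(derandomize=True, max_examples=30)
@given(samples=st.lists(reads_strategy, min_size=1, max_size=4), k=st.integers(1, 6))
def test_count_conservation_per_sample(samples, k):
    """Sum of counts in sample i equals sum over reads of max(len-k+1, 0)."""
    table = KmerFrequencyTable.from_reads(samples, k)
    totals = table.sample_totals() if len(table) else np.zeros(len(samples))
    for i, reads in enumerate(samples):
        assert totals[i] == sum(max(len(r) - k + 1, 0) for r in reads)


@settings(derandomize=True, max_examples=25)
@given(samples=st.lists(reads_strategy, min_size=1, max_size=3), k=st.integers(1, 5))
def test_from_reads_equals_merged_dict_counts(samples, k):
    """Vectorised counting agrees with per-read dict enumeration."""
    fast = KmerFrequencyTable.from_reads(samples, k)
    maps = [dict_count([r.upper() for r in reads], k) for reads in samples]
    if not any(maps):
        assert len(fast) == 0
        return
    slow = merge_counts(maps, k=k)
    assert len(fast) == len(slow)
    for km in slow:
        assert fast[km].tolist() == slow[km].tolist()


# ---------------------------------------------------------------- significance


@pytest.mark.parametrize(
    "vec,tau,expected",
    [
        ((1000, 2000, 25000), 1, True),  # worked example: |log10 c1 - log10 c3| >= 1
        ((0, 0, 0), 1, False),
        ((50, 50), 1, False),
        ((0, 10), 1, True),
        ((10,), 1, False),  # single sample: no pair exists
        ((9, 0), 1, False),  # log10(9) < 1
        ((1, 10), 1, True),
        ((1, 9), 1, False),
    ],
)
def test_is_significant_cases(vec, tau, expected):
    assert is_significant(vec, tau) is expected


def test_is_significant_rejects_bad_tau():
    for tau in (0, -1):
        with pytest.raises(ValueError):
            is_significant([1, 10], tau)


def _random_table(rng, n_kmers, n_samples):
    alphabet = "ACGT"
    kmers = set()
    while len(kmers) < n_kmers:
        kmers.add("".join(rng.choice(alphabet) for _ in range(8)))
    rows = {}
    for km in kmers:
        rows[km] = [
            0 if rng.random() < 0.4 else int(10 ** (rng.random() * 4))
            for _ in range(n_samples)
        ]
    return rows


@pytest.mark.parametrize("tau", [0.5, 1.0, 2.0])
def test_significant_kmers_matches_brute_force(tau):
    """Vectorised selection equals literal all-pairs evaluation."""
    rng = random.Random(7)
    rows = _random_table(rng, 400, 5)
    maps = [{km: v[i] for km, v in rows.items() if v[i]} for i in range(5)]
    table = merge_counts(maps, k=8)
    psi = significant_kmers(table, tau)
    expected = {km for km, v in rows.items() if brute_force_significant(v, tau)}
    assert set(psi.kmers) == expected
    # every member satisfies the predicate against its own table
    assert all(is_significant(table[km], tau) for km in psi)


def test_tau_monotonicity():
    rng = random.Random(11)
    rows = _random_table(rng, 200, 4)
    maps = [{km: v[i] for km, v in rows.items() if v[i]} for i in range(4)]
    table = merge_counts(maps, k=8)
    previous = None
    for tau in (0.3, 0.7, 1.0, 1.5, 2.5):
        current = set(significant_kmers(table, tau).kmers)
        if previous is not None:
            assert current <= previous
        previous = current


def test_sample_permutation_invariance():
    rng = random.Random(3)
    rows = _random_table(rng, 100, 3)
    maps = [{km: v[i] for km, v in rows.items() if v[i]} for i in range(3)]
    table = merge_counts(maps, k=8)
    perm = [2, 0, 1]
    table_p = merge_counts([maps[i] for i in perm], k=8)
    for km in table:
        assert table_p[km].tolist() == [int(table[km][i]) for i in perm]
    assert set(significant_kmers(table, 1.0).kmers) == set(
        significant_kmers(table_p, 1.0).kmers
    )


@pytest.mark.parametrize("tau", [0.5, 1.0])
def test_streaming_selection_equals_table_path(tau):
    """The two-pass candidate-pruned path returns exactly the table-based set."""
    rng = np.random.default_rng(5)
    base = "".join("ACGT"[b] for b in rng.integers(0, 4, 60))
    samples = []
    for i in range(3):
        reads = ["".join("ACGT"[b] for b in rng.integers(0, 4, 40)) for _ in range(30)]
        reads += [base] * (3 + 30 * i)  # enriched shared sequence
        samples.append(reads)
    streamed = find_significant_kmers(samples, 7, tau)
    table = KmerFrequencyTable.from_reads(samples, 7)
    direct = significant_kmers(table, tau)
    assert set(streamed.kmers) == set(direct.kmers)
    assert len(direct) > 0  # the enriched sequence must register


def test_table_tsv_roundtrip(tmp_path):
    table = merge_counts([{"ACGTN": 2, "TTTTT": 1}, {"ACGTN": 7}])
    path = tmp_path / "kmers.tsv"
    table.to_tsv(path)
    back = KmerFrequencyTable.from_tsv(path)
    assert len(back) == len(table)
    for km in table:
        assert back[km].tolist() == table[km].tolist()
    assert path.read_text().startswith("#")
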