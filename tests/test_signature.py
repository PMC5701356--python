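"""Step 2: signature construction, the similarity threshold, and correction."""

import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonesift.kmer import SignificantKmerSet
from clonesift.signature import (
    ScoringParams,
    Signature,
    SignatureSet,
    are_similar,
    build_signature,
    collect_signatures,
    correct_signatures,
    similarity_threshold,
    sw_score,
)


def psi_of(kmers, k, tau=1.0):
    return SignificantKmerSet(k=k, tau=tau, kmers=frozenset(kmers))


def oracle_signature(read, kmers, k):
    """Coverage-array implementation of the interval-union rule."""
    covered = [False] * len(read)
    for p in range(len(read) - k + 1):
        if read[p : p + k] in kmers:
            for q in range(p, p + k):
                covered[q] = True
    out, run = [], []
    for ch, cov in zip(read, covered):
        if cov:
            run.append(ch)
        elif run:
            out.append("".join(run))
            run = []
    if run:
        out.append("".join(run))
    return "".join(out)


# ---------------------------------------------------------------- signatures


def test_build_signature_interval_union_on_worked_example():
    """For read ATCCCGTC with significant k-mers {CCC, CCG, CGT} (k=3) the
    covered positions are 3..7, so the interval-union signature is CCCGT.

    Note: the originally circulated worked example prints CCGT for this
    input, which no positional combination of those three k-mers can
    produce (their spans overlap as 3-5, 4-6, 5-7); the implemented rule
    is the interval union, and this test documents the discrepancy.
    """
    psi = psi_of({"CCC", "CCG", "CGT"}, 3)
    assert build_signature("ATCCCGTC", psi) == "CCCGT"


def test_build_signature_empty_when_no_significant_kmer():
    assert build_signature("ATCCCGTC", psi_of({"GGG"}, 3)) == ""


def test_build_signature_concatenates_disjoint_segments():
    psi = psi_of({"AAAA", "GGGG"}, 4)
    assert build_signature("AAAATTTTGGGG", psi) == "AAAAGGGG"


@settings(derandomize=True, max_examples=40)
@given(data=st.data())
def test_build_signature_matches_coverage_oracle(data):
    rng = random.Random(data.draw(st.integers(0, 10**6)))
    k = rng.randint(2, 5)
    read = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 30)))
    all_kmers = {read[p : p + k] for p in range(len(read) - k + 1)}
    chosen = {km for km in all_kmers if rng.random() < 0.5}
    chosen.add("".join(rng.choice("ACGT") for _ in range(k)))  # maybe absent
    psi = psi_of(chosen, k)
    assert build_signature(read, psi) == oracle_signature(read, chosen, k)


def test_collect_signatures_pools_identical_reads():
    psi = psi_of({"AAAA"}, 4)
    sset = collect_signatures(["GAAAAG"] * 10, psi)
    assert len(sset) == 1
    assert sset.signatures[0].frequency == 10
    assert sset.signatures[0].sequence == "AAAA"
    assert sset.signatures[0].exemplar_read == "GAAAAG"
    assert sset.n_empty_reads == 0


def test_collect_signatures_counts_empty_reads_and_keeps_first_exemplar():
    psi = psi_of({"AAAA", "CCCC"}, 4)
    reads = ["TAAAAT", "GGGGGG", "CCCCTT", "AAAAGG"]
    sset = collect_signatures(reads, psi)
    assert sset.n_empty_reads == 1
    by_seq = {s.sequence: s for s in sset.signatures}
    assert by_seq["AAAA"].frequency == 2
    assert by_seq["AAAA"].exemplar_read == "TAAAAT"
    assert by_seq["CCCC"].frequency == 1


def test_collect_signatures_separates_two_clones():
    psi = psi_of({"AAAAA", "GGGGG"}, 5)
    reads = ["TTAAAAATT"] * 80 + ["TTGGGGGTT"] * 20
    sset = collect_signatures(reads, psi)
    freqs = sorted((s.sequence, s.frequency) for s in sset.signatures)
    assert freqs == [("AAAAA", 80), ("GGGGG", 20)]


# ---------------------------------------------------------------- threshold

# Hand-computed two-branch values with defaults M=MM=2, IN=3:
# branch 1 (0.7*max > min): T = 2*max; branch 2: T = 0.92*max.
HAND_COMPUTED_T = [
    (10, 6, 20.0),
    (10, 7, 9.2),
    (10, 10, 9.2),
    (1, 1, 0.92),
    (5, 3, 10.0),
    (8, 8, 7.36),
    (20, 14, 18.4),
    (20, 13, 40.0),
    (50, 40, 46.0),
    (50, 34, 100.0),
    (30, 29, 27.6),
    (100, 60, 200.0),
    (100, 70, 92.0),
    (100, 71, 92.0),
    (300, 211, 276.0),
    (300, 209, 600.0),
    (12, 9, 11.04),
    (12, 8, 24.0),
    (40, 28, 36.8),
    (7, 5, 6.44),
]


@pytest.mark.parametrize("la,lb,expected", HAND_COMPUTED_T)
def test_similarity_threshold_two_branch_formula(la, lb, expected, params):
    assert similarity_threshold(la, lb, params) == pytest.approx(expected)
    assert similarity_threshold(lb, la, params) == pytest.approx(expected)


def test_similarity_threshold_nondefault_params():
    p = ScoringParams(match=3, mismatch=1, indel=0)
    # coefficient = 3*4/5 - 1*2/50 - 0 = 2.36
    assert similarity_threshold(10, 10, p) == pytest.approx(23.6)


def test_short_vs_long_branch_is_unreachable(params):
    # (10, 6): T = 20 exceeds the maximum attainable score 2*6 = 12
    assert similarity_threshold(10, 6, params) > params.match * 6


@settings(derandomize=True, max_examples=60)
@given(data=st.data())
def test_seventy_percent_rule_blocks_any_merge(data):
    """Pairs whose shorter length < 0.7x the longer are never similar,
    whatever their content."""
    rng = random.Random(data.draw(st.integers(0, 10**6)))
    hi = rng.randint(3, 60)
    lo = rng.randint(1, max(int(0.7 * hi) - 1, 1))
    if hi * 0.7 <= lo:
        lo = max(1, int(0.7 * hi) - 1)
    a = "".join(rng.choice("ACGT") for _ in range(hi))
    b = a[:lo]  # maximally similar content
    assert not are_similar(a, b, ScoringParams())


def test_identical_sequences_are_similar(params):
    s = "ACGTACGTACGTACGTACGT"
    assert are_similar(s, s, params)  # score 2L > 0.92L


def test_lengths_100_vs_60_never_similar(params):
    rng = random.Random(0)
    a = "".join(rng.choice("ACGT") for _ in range(100))
    assert not are_similar(a, a[:60], params)


def test_one_mismatch_in_twenty_is_similar(params):
    a = "ACGTACGTACGTACGTACGT"
    b = a[:10] + ("C" if a[10] != "C" else "G") + a[11:]
    assert sw_score(a, b, params) == 36  # 19 matches, 1 mismatch
    assert similarity_threshold(20, 20, params) == pytest.approx(18.4)
    assert are_similar(a, b, params)


def test_zero_penalties_make_identical_strings_always_similar():
    p = ScoringParams(match=2, mismatch=0, indel=0)
    for n in (1, 5, 200):
        s = "A" * n
        assert are_similar(s, s, p)  # T = 1.6n < 2n


# ---------------------------------------------------------------- correction


def sig_set(pairs):
    return SignatureSet(signatures=[Signature(s, f) for s, f in pairs])


def test_correction_absorbs_lower_frequency_into_higher(params):
    a = "ACGTACGTACGTACGTACGT"
    b = a[:10] + "C" + a[11:] if a[10] != "C" else a[:10] + "G" + a[11:]
    out = correct_signatures(sig_set([(a, 100), (b, 3)]), params)
    assert len(out) == 1
    assert out.signatures[0].sequence == a  # higher-frequency member survives
    assert out.signatures[0].frequency == 103


def test_correction_leaves_dissimilar_set_unchanged(params):
    pairs = [("AAAAAAAAAA", 5), ("CCCCCCCCCC", 4), ("GGGGGGGGGG", 3)]
    out = correct_signatures(sig_set(pairs), params)
    assert sorted((s.sequence, s.frequency) for s in out.signatures) == sorted(pairs)


def test_correction_tie_breaks_to_lexicographically_smaller(params):
    a = "ACGTACGTACGTACGTACGT"
    b = a[:-1] + "C" if a[-1] != "C" else a[:-1] + "G"
    lo, hi = sorted([a, b])
    out = correct_signatures(sig_set([(a, 7), (b, 7)]), params)
    assert len(out) == 1 and out.signatures[0].sequence == lo


@settings(derandomize=True, max_examples=25, deadline=None)
@given(data=st.data())
def test_correction_conserves_total_frequency_and_is_idempotent(data):
    rng = random.Random(data.draw(st.integers(0, 10**6)))
    base = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 25)))
    pairs = Counter()
    for _ in range(rng.randint(1, 12)):
        seq = list(base)
        for _ in range(rng.randint(0, 3)):
            pos = rng.randrange(len(seq))
            seq[pos] = rng.choice("ACGT")
        pairs["".join(seq[: rng.randint(max(1, len(seq) - 4), len(seq))])] += (
            rng.randint(1, 50)
        )
    sset = sig_set(list(pairs.items()))
    total = sset.total_frequency()
    once = correct_signatures(sset, ScoringParams())
    assert once.total_frequency() == total
    twice = correct_signatures(once, ScoringParams())
    assert [(s.sequence, s.frequency) for s in twice.signatures] == [
        (s.sequence, s.frequency) for s in once.signatures
    ]
    # no similar pair survives
    for i, s1 in enumerate(once.signatures):
        for s2 in once.signatures[i + 1 :]:
            assert not are_similar(s1, s2, ScoringParams())


def test_correction_collapses_noisy_clone_copies(params):
    """1000 reads of one clone with 1% substitution noise collapse to a
    dominant signature whose frequency is conserved at 1000."""
    rng = random.Random(42)
    clone = "".join(rng.choice("ACGT") for _ in range(60))
    counted = Counter()
    for _ in range(1000):
        seq = list(clone)
        for p in range(len(seq)):
            if rng.random() < 0.01:
                seq[p] = rng.choice("ACGT")
        counted["".join(seq)] += 1
    out = correct_signatures(sig_set(list(counted.items())), params)
    assert out.total_frequency() == 1000
    top = max(out.signatures, key=lambda s: s.frequency)
    assert top.sequence == clone
    assert top.frequency >= 900


def test_signature_set_tsv_roundtrip(tmp_path):
    sset = SignatureSet(
        sample_index=2,
        signatures=[Signature("ACGT", 5, "TTACGTTT"), Signature("GGGG", 1, "GGGG")],
        n_empty_reads=7,
    )
    path = tmp_path / "sigs.tsv"
    sset.to_tsv(path)
    back = SignatureSet.from_tsv(path)
    assert back.sample_index == 2 and back.n_empty_reads == 7
    assert [(s.sequence, s.frequency, s.exemplar_read) for s in back.signatures] == [
        (s.sequence, s.frequency, s.exemplar_read) for s in sset.signatures
    ]
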