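"""Synthetic VDJ-rearranged amplicon reads with known clonal composition.

The generator emulates the artificial-dilution study design used to
validate MRD pipelines: a dominant tumour clone — one fixed VDJ
rearrangement with junctional deletions and random N-region insertions —
is spiked at controlled fractions into a polyclonal background in which
every read is a fresh random rearrangement (so no background clonotype
ever reaches a meaningful frequency, like pooled healthy-donor
"buffycoat" DNA).  Sequencing noise is modelled as per-base
substitutions plus N-masking applied in geometric-length runs whose
marginal per-base rate is ``n_rate``, reproducing the degraded regime
of low-input libraries: bursts of unknown base calls dominate the
quality profile while long clean stretches survive between them.

Everything is driven by numpy Generators, so a fixed seed reproduces
the output byte for byte.  Quality strings are constant placeholders:
the pipeline never reads them, and quality degradation is expressed
through the explicit N-masking rate instead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .annotate import GermlineSegment, load_germline

__all__ = [
    "CloneSpec",
    "SimulationConfig",
    "make_toy_germline",
    "toy_germline",
    "default_clone_spec",
    "simulate_rearrangement",
    "simulate_sample",
    "dilution_series",
]

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3, 78: 4}


@dataclass(frozen=True)
class CloneSpec:
    """One clone's rearrangement recipe: segment choices, trims, insert sizes."""

    v: str
    d: str
    j: str
    v_del: int = 4  # bases trimmed from the V 3' end
    d_del5: int = 2  # bases trimmed from the D 5' end
    d_del3: int = 3  # bases trimmed from the D 3' end
    j_del: int = 3  # bases trimmed from the J 5' end
    n1: int = 8  # random N-region insert between V and D
    n2: int = 5  # random N-region insert between D and J


@dataclass
class SimulationConfig:
    """Study conditions for one simulated patient.

    ``germline`` may be a grouped segment dict (as returned by
    :func:`clonesift.annotate.load_germline`) or None to use the
    packaged toy germline derived from ``germline_seed``.
    """

    clones: dict = field(default_factory=dict)  # clone_id -> CloneSpec
    germline: dict | None = None
    germline_seed: int = 0
    reads_per_sample: int = 100_000
    sub_rate: float = 0.005
    n_rate: float = 0.0
    n_burst_len: float = 8.0  # mean length of N-call runs
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.sub_rate <= 1 or not 0 <= self.n_rate <= 1:
            raise ValueError("error rates must lie in [0, 1]")

    def germline_groups(self) -> dict[str, list[GermlineSegment]]:
        if self.germline is None:
            self.germline = toy_germline(self.germline_seed)
        return self.germline


def make_toy_germline(seed: int = 0) -> str:
    """Deterministic toy germline FASTA: 5 V (250 nt), 4 D (15-30 nt), 4 J (50 nt).

    Segments are independent uniform-random sequences, so pairwise V
    identities stay far below 90% and assignments are unambiguous.
    Headers follow the IMGT GENE-DB pipe dialect.
    """
    rng = np.random.default_rng(seed)
    records = []
    acc = 0
    for i in range(5):
        seq = _BASES[rng.integers(0, 4, size=250)].tobytes().decode()
        records.append((f"IGHV{i + 1}-1*01", "V", seq))
    for i in range(4):
        length = int(rng.integers(15, 31))
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        records.append((f"IGHD{i + 1}-1*01", "D", seq))
    for i in range(4):
        seq = _BASES[rng.integers(0, 4, size=50)].tobytes().decode()
        records.append((f"IGHJ{i + 1}*01", "J", seq))
    lines = []
    for name, cls, seq in records:
        acc += 1
        lines.append(f">TOY{acc:05d}|{name}|Homo sapiens|F|{cls}-REGION|synthetic")
        lines.append(seq)
    return "\n".join(lines) + "\n"


def toy_germline(seed: int = 0) -> dict[str, list[GermlineSegment]]:
    """The toy germline parsed into grouped segments."""
    return load_germline(io.StringIO(make_toy_germline(seed)))


def default_clone_spec(clone_id: int = 0) -> CloneSpec:
    """A ready-made clone recipe over the toy germline."""
    picks = [
        ("IGHV3-1*01", "IGHD2-1*01", "IGHJ3*01"),
        ("IGHV1-1*01", "IGHD4-1*01", "IGHJ1*01"),
        ("IGHV5-1*01", "IGHD1-1*01", "IGHJ4*01"),
    ]
    v, d, j = picks[clone_id % len(picks)]
    return CloneSpec(v=v, d=d, j=j)


def _segment(groups, cls: str, name: str) -> str:
    for seg in groups[cls]:
        if seg.gene_name == name:
            return seg.sequence
    raise KeyError(f"no {cls} segment named {name!r} in the germline")


def _random_insert(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode() if n else ""


def simulate_rearrangement(
    config: SimulationConfig, clone_id, rng: np.random.Generator
) -> str:
    """Build one clone's rearranged sequence: V' + N1 + D'' + N2 + J'.

    Trims shorten the segment ends facing the junction; N1/N2 are
    uniform-random inserts drawn from *rng* (the junction is therefore
    reproducible only under a fixed generator state).
    """
    spec = config.clones[clone_id]
    groups = config.germline_groups()
    v = _segment(groups, "V", spec.v)
    d = _segment(groups, "D", spec.d)
    j = _segment(groups, "J", spec.j)
    if spec.v_del >= len(v) or spec.j_del >= len(j):
        raise ValueError("trim length exceeds segment length")
    if spec.d_del5 + spec.d_del3 >= len(d):
        raise ValueError("D trims leave no D sequence")
    if min(spec.v_del, spec.d_del5, spec.d_del3, spec.j_del, spec.n1, spec.n2) < 0:
        raise ValueError("trims and insert lengths must be >= 0")
    return (
        v[: len(v) - spec.v_del]
        + _random_insert(rng, spec.n1)
        + d[spec.d_del5 : len(d) - spec.d_del3]
        + _random_insert(rng, spec.n2)
        + j[spec.j_del :]
    )


def clone_sequences(config: SimulationConfig) -> dict:
    """The fixed clone sequences of a run, derived from ``config.seed``.

    A dedicated generator keyed on the seed makes clone junctions
    identical across all samples of a series regardless of how many
    reads each sample draws.
    """
    rng = np.random.default_rng([config.seed, 101])
    return {cid: simulate_rearrangement(config, cid, rng) for cid in config.clones}


def _random_rearrangement(groups, rng: np.random.Generator) -> str:
    """One fresh polyclonal-background rearrangement."""
    v = groups["V"][int(rng.integers(0, len(groups["V"])))].sequence
    d = groups["D"][int(rng.integers(0, len(groups["D"])))].sequence
    j = groups["J"][int(rng.integers(0, len(groups["J"])))].sequence
    v_del = int(rng.integers(0, 13))
    d5 = int(rng.integers(0, min(6, len(d))))
    d3 = int(rng.integers(0, max(len(d) - d5 - 1, 1)))
    j_del = int(rng.integers(0, 10))
    n1 = int(rng.integers(0, 13))
    n2 = int(rng.integers(0, 13))
    return (
        v[: len(v) - v_del]
        + _random_insert(rng, n1)
        + d[d5 : len(d) - d3]
        + _random_insert(rng, n2)
        + j[j_del:]
    )


def _burst_mask(shape, rng, n_rate: float, mean_len: float) -> np.ndarray:
    """Boolean N-call mask made of geometric-length bursts.

    Burst starts are Bernoulli per base at rate -ln(1-n_rate)/mean_len,
    which makes the stationary per-base coverage probability equal
    n_rate (Boolean-model identity P(uncovered) = exp(-rate*mean)).
    Bursts reproduce the run structure of quality crashes: the marginal
    N rate matches an i.i.d. model, but long clean stretches survive.
    """
    if n_rate >= 1.0:
        return np.ones(shape, dtype=bool)
    m, L = shape
    p_start = -np.log1p(-n_rate) / mean_len
    starts = rng.random(shape) < p_start
    ri, ci = np.nonzero(starts)
    delta = np.zeros((m, L + 1), dtype=np.int32)
    if ri.size:
        lengths = rng.geometric(1.0 / mean_len, size=ri.size)
        np.add.at(delta, (ri, ci), 1)
        np.add.at(delta, (ri, np.minimum(ci + lengths, L)), -1)
    return np.cumsum(delta[:, :L], axis=1) > 0


def _mutate_matrix(
    mat: np.ndarray, rng, sub_rate: float, n_rate: float, n_burst_len: float
) -> np.ndarray:
    """Apply substitutions then N-masking bursts to an (m, L) code matrix in place."""
    if sub_rate > 0:
        mask = rng.random(mat.shape) < sub_rate
        k = int(mask.sum())
        if k:
            # replace with a uniformly random *different* ACGT base
            mat[mask] = (mat[mask] + 1 + rng.integers(0, 3, size=k)) % 4
    if n_rate > 0:
        mat[_burst_mask(mat.shape, rng, n_rate, n_burst_len)] = 4
    return mat


def _decode_rows(mat: np.ndarray) -> list[str]:
    m, L = mat.shape
    blob = _BASES[mat].tobytes().decode()
    return [blob[i * L : (i + 1) * L] for i in range(m)]


def simulate_sample(
    config: SimulationConfig,
    fractions: dict,
    rng: np.random.Generator,
    n_reads: int | None = None,
    sample_name: str = "sample",
) -> tuple[str, dict]:
    """One sample's FASTQ plus its ground-truth read counts per clone.

    Each read is independently assigned to a clone according to
    *fractions* (clone_id -> fraction); the remainder is polyclonal
    background, one fresh rearrangement per read.  Substitution errors
    are applied first, N-masking second, to every read.  Returns
    ``(fastq_text, true_counts)`` with ``true_counts`` keyed by clone id
    plus ``"background"``.
    """
    if n_reads is None:
        n_reads = config.reads_per_sample
    ids = list(fractions)
    probs = np.array([fractions[c] for c in ids], dtype=float)
    if (probs < 0).any() or probs.sum() > 1 + 1e-9:
        raise ValueError("clone fractions must be non-negative and sum to <= 1")
    groups = config.germline_groups()
    templates = clone_sequences(config)

    p = np.append(probs, max(1.0 - probs.sum(), 0.0))
    p = p / p.sum()
    choice = rng.choice(len(ids) + 1, size=n_reads, p=p)

    seqs: list[str | None] = [None] * n_reads
    true_counts = {}
    for ci, cid in enumerate(ids):
        idx = np.flatnonzero(choice == ci)
        true_counts[cid] = int(idx.size)
        if not idx.size:
            continue
        template = np.array([_CODE[b] for b in templates[cid].encode()], dtype=np.uint8)
        mat = np.tile(template, (idx.size, 1))
        _mutate_matrix(mat, rng, config.sub_rate, config.n_rate, config.n_burst_len)
        for i, read in zip(idx, _decode_rows(mat)):
            seqs[i] = read
    bg_idx = np.flatnonzero(choice == len(ids))
    true_counts["background"] = int(bg_idx.size)
    for i in bg_idx:
        raw = _random_rearrangement(groups, rng)
        row = np.array([_CODE[b] for b in raw.encode()], dtype=np.uint8)[None, :]
        _mutate_matrix(row, rng, config.sub_rate, config.n_rate, config.n_burst_len)
        seqs[i] = _decode_rows(row)[0]

    lines = []
    for i, seq in enumerate(seqs):
        lines.append(f"@{sample_name}_{i + 1}")
        lines.append(seq)
        lines.append("+")
        lines.append("I" * len(seq))
    return "\n".join(lines) + ("\n" if lines else ""), true_counts


def dilution_series(
    config: SimulationConfig,
    fractions: list[float],
    rng: np.random.Generator,
    sample_names: list[str] | None = None,
) -> tuple[list[str], dict]:
    """A multi-sample series sharing one spiked clone, plus a truth manifest.

    ``fractions[i]`` is the spiked clone's fraction in sample i; the
    first sample is conventionally the diagnostic.  The spiked clone is
    the first entry of ``config.clones``.  Returns ``(fastq_texts,
    manifest)`` where the manifest records clone sequences, per-sample
    intended fractions and realised read counts.
    """
    if not config.clones:
        raise ValueError("config defines no clones to spike")
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    spike = next(iter(config.clones))
    if sample_names is None:
        sample_names = [f"S{i + 1}" for i in range(len(fractions))]
    samples, sample_meta = [], []
    for name, frac in zip(sample_names, fractions):
        fastq, truth = simulate_sample(
            config, {spike: frac}, rng, sample_name=name
        )
        samples.append(fastq)
        sample_meta.append(
            {
                "name": name,
                "n_reads": config.reads_per_sample,
                "spike_fraction": frac,
                "true_counts": truth,
            }
        )
    manifest = {
        "spike_clone": spike,
        "clones": dict(clone_sequences(config)),
        "clone_specs": {
            cid: spec.__dict__ for cid, spec in config.clones.items()
        },
        "sub_rate": config.sub_rate,
        "n_rate": config.n_rate,
        "seed": config.seed,
        "samples": sample_meta,
    }
    return samples, manifest
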