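"""Step 3 (accumulation) — merge per-sample signature sets into clones.

The corrected signature sets Gamma_1..Gamma_n are folded, in sample
order, into a single table Delta of putative clones.  Each signature is
matched against the existing clones with the same similarity predicate
used for within-sample correction; a match adds the signature's
frequency to that clone's entry for the contributing sample, otherwise
the signature founds a new clone whose frequency vector is zero
everywhere else.  A clone's representative sequence never changes after
insertion — the first sample to contribute it defines the sequence.

When a signature is similar to several clones it is assigned to the
highest-scoring one (ties: higher total frequency, then lexicographic
sequence), so the dominant clone keeps attracting its error halo across
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from ._encode import seq_to_codes
from .align import PaddedSeqs, _scores_vs_many
from .signature import ScoringParams, SignatureSet, similarity_threshold

if TYPE_CHECKING:  # pragma: no cover
    from .annotate import VdjAnnotation

__all__ = ["Clone", "CloneTable", "accumulate_clones", "frequency_matrix"]


@dataclass
class Clone:
    """A putative clonotype with its n-sample frequency vector."""

    sequence: str
    freq_vector: np.ndarray
    exemplar_read: str = ""
    annotation: Optional["VdjAnnotation"] = None

    def __post_init__(self):
        self.freq_vector = np.asarray(self.freq_vector, dtype=np.int64)
        if self.freq_vector.ndim != 1:
            raise ValueError("freq_vector must be one-dimensional")

    @property
    def total_frequency(self) -> int:
        return int(self.freq_vector.sum())


@dataclass
class CloneTable:
    """The clone set Delta for one patient, with sample bookkeeping.

    ``diagnostic_index`` is the 0-based position of the diagnostic
    sample in ``sample_labels``.  ``sample_totals`` holds the total read
    count of each sample (needed for relative abundances downstream).
    """

    clones: list[Clone] = field(default_factory=list)
    sample_labels: list[str] = field(default_factory=list)
    diagnostic_index: int = 0
    sample_totals: Optional[np.ndarray] = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    def __len__(self) -> int:
        return len(self.clones)

    def per_sample_clone_totals(self) -> np.ndarray:
        if not self.clones:
            return np.zeros(self.n_samples, dtype=np.int64)
        return np.sum([c.freq_vector for c in self.clones], axis=0)

    def subset(self, clones: list[Clone]) -> "CloneTable":
        return CloneTable(
            clones=clones,
            sample_labels=self.sample_labels,
            diagnostic_index=self.diagnostic_index,
            sample_totals=self.sample_totals,
        )


def accumulate_clones(
    signature_sets: list[SignatureSet],
    params: ScoringParams = ScoringParams(),
    sample_labels: list[str] | None = None,
    diagnostic_index: int = 0,
    sample_totals=None,
) -> CloneTable:
    """Fold corrected signature sets, in order, into a clone table.

    Per-sample conservation holds on output: the clone frequencies of
    sample i sum to the signature frequencies of Gamma_i.  Within each
    set, signatures are processed in descending-frequency order (ties:
    lexicographic) for determinism.
    """
    n = len(signature_sets)
    if n < 1:
        raise ValueError("need at least one signature set")
    if sample_labels is None:
        sample_labels = [f"S{i + 1}" for i in range(n)]
    if len(sample_labels) != n:
        raise ValueError("one label per signature set required")
    if not 0 <= diagnostic_index < n:
        raise ValueError("diagnostic_index out of range")

    clones: list[Clone] = []
    pack = PaddedSeqs()
    for i, sset in enumerate(signature_sets):
        ordered = sorted(sset.signatures, key=lambda s: (-s.frequency, s.sequence))
        for sig in ordered:
            target = None
            if clones:
                scores = _scores_vs_many(
                    seq_to_codes(sig.sequence),
                    pack.mat,
                    pack.lens,
                    params.match,
                    params.mismatch,
                    params.indel,
                    params.length_ratio_cutoff,
                )
                best_score = -1
                for r in np.flatnonzero(scores >= 0):
                    clone = clones[r]
                    T = similarity_threshold(
                        len(sig.sequence), len(clone.sequence), params
                    )
                    s = int(scores[r])
                    if s <= T:
                        continue
                    if target is None or s > best_score:
                        target, best_score = clone, s
                    elif s == best_score and (
                        clone.total_frequency > target.total_frequency
                        or (
                            clone.total_frequency == target.total_frequency
                            and clone.sequence < target.sequence
                        )
                    ):
                        target = clone
            if target is not None:
                target.freq_vector[i] += sig.frequency
            else:
                vec = np.zeros(n, dtype=np.int64)
                vec[i] = sig.frequency
                clones.append(Clone(sig.sequence, vec, sig.exemplar_read))
                pack.append(sig.sequence)
    totals = None if sample_totals is None else np.asarray(sample_totals, np.int64)
    return CloneTable(
        clones=clones,
        sample_labels=list(sample_labels),
        diagnostic_index=diagnostic_index,
        sample_totals=totals,
    )


def frequency_matrix(table: CloneTable) -> pd.DataFrame:
    """Clones-by-samples count matrix, plus a totals row.

    Rows are ordered by descending diagnostic-sample frequency, ties
    broken lexicographically by sequence; the appended ``TOTAL`` row
    holds per-sample sums.
    """
    ordered = sorted(
        table.clones,
        key=lambda c: (-int(c.freq_vector[table.diagnostic_index]), c.sequence),
    )
    data = (
        np.vstack([c.freq_vector for c in ordered])
        if ordered
        else np.zeros((0, table.n_samples), dtype=np.int64)
    )
    df = pd.DataFrame(
        data, index=[c.sequence for c in ordered], columns=table.sample_labels
    )
    df.loc["TOTAL"] = data.sum(axis=0) if len(ordered) else 0
    return df
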