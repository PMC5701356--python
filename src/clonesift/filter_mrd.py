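"""Two-phase clone filtering, major-clone selection and MRD quantification.

Phase-A keeps clones whose diagnostic-sample frequency strictly exceeds
a read-count threshold (default 100 reads — the working equivalent of
the "5% of reads" predominance rule for these amplicon runs).  Phase-B
keeps clones whose best germline identity strictly exceeds a homology
threshold (default 0.80) in all three of V, D and J simultaneously.

MRD for the major clone is its per-sample relative abundance
a_i = reads_i / total_i rescaled to a diagnostic anchor (e.g. the
ASO q-PCR value at diagnosis):  m_i = baseline * a_i / a_diag, so the
diagnostic sample sits exactly at the baseline and follow-ups read as
tumour-burden levels on the qPCR scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clone import Clone, CloneTable

__all__ = [
    "FilterConfig",
    "MrdSeries",
    "phase_a",
    "phase_b",
    "major_clone",
    "mrd_series",
]


@dataclass(frozen=True)
class FilterConfig:
    min_diag_reads: int = 100
    min_identity: float = 0.80

    def __post_init__(self):
        if self.min_diag_reads < 0:
            raise ValueError("min_diag_reads must be >= 0")
        if not 0 <= self.min_identity <= 1:
            raise ValueError("min_identity must be in [0, 1]")


def phase_a(table: CloneTable, config: FilterConfig = FilterConfig()) -> CloneTable:
    """Keep clones with diagnostic frequency strictly above the threshold."""
    if not 0 <= table.diagnostic_index < max(table.n_samples, 1):
        raise ValueError("table has an invalid diagnostic_index")
    kept = [
        c
        for c in table.clones
        if c.freq_vector[table.diagnostic_index] > config.min_diag_reads
    ]
    return table.subset(kept)


def phase_b(table: CloneTable, config: FilterConfig = FilterConfig()) -> CloneTable:
    """Keep clones strictly above the identity threshold in V, D and J.

    Requires every clone to be annotated; raises otherwise.
    """
    for c in table.clones:
        if c.annotation is None:
            raise ValueError(
                f"clone {c.sequence[:24]}... is unannotated; run annotation "
                "before Phase-B"
            )
    kept = [
        c
        for c in table.clones
        if all(
            c.annotation.identity(cls) > config.min_identity for cls in ("V", "D", "J")
        )
    ]
    return table.subset(kept)


def major_clone(table: CloneTable) -> Clone:
    """The clone with the highest diagnostic-sample frequency (ties: lexicographic)."""
    if not table.clones:
        raise LookupError("clone table is empty; no major clone exists")
    return min(
        table.clones,
        key=lambda c: (-int(c.freq_vector[table.diagnostic_index]), c.sequence),
    )


@dataclass
class MrdSeries:
    """Per-sample abundance and baseline-scaled MRD level of one clone.

    ``flags`` is one of ``ok``, ``not_detected`` (zero reads) or
    ``undefined`` (sample with zero total reads; abundance/level are NaN
    there, never silently 0).
    """

    clone: Clone
    sample_labels: list[str]
    counts: np.ndarray
    totals: np.ndarray
    abundance: np.ndarray
    scaled: np.ndarray
    baseline: float
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_labels,
                "reads": self.counts,
                "total_reads": self.totals,
                "abundance": self.abundance,
                "mrd_level": self.scaled,
                "flag": self.flags,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        def _clean(x):
            return None if np.isnan(x) else float(x)

        return {
            "clone": self.clone.sequence,
            "baseline": self.baseline,
            "samples": [
                {
                    "sample": lab,
                    "reads": int(c),
                    "total_reads": int(t),
                    "abundance": _clean(a),
                    "mrd_level": _clean(m),
                    "flag": f,
                }
                for lab, c, t, a, m, f in zip(
                    self.sample_labels,
                    self.counts,
                    self.totals,
                    self.abundance,
                    self.scaled,
                    self.flags,
                )
            ],
        }


def mrd_series(
    clone: Clone, table: CloneTable, baseline: float = 1.0
) -> MrdSeries:
    """Baseline-scaled MRD levels of *clone* across the table's samples.

    ``m_i = baseline * a_i / a_diag`` with ``a_i`` the clone's relative
    abundance in sample i; the diagnostic sample is exactly at the
    baseline.  The table must carry per-sample total read counts.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if table.sample_totals is None:
        raise ValueError("table has no per-sample total read counts")
    totals = np.asarray(table.sample_totals, dtype=np.int64)
    counts = np.asarray(clone.freq_vector, dtype=np.int64)
    if counts.shape[0] != totals.shape[0]:
        raise ValueError("clone vector and totals have different lengths")

    with np.errstate(divide="ignore", invalid="ignore"):
        abundance = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    a_diag = abundance[table.diagnostic_index]
    if not np.isfinite(a_diag) or a_diag <= 0:
        raise ValueError(
            "major clone has zero abundance in the diagnostic sample; "
            "cannot anchor the MRD proportion"
        )
    scaled = baseline * abundance / a_diag
    scaled[table.diagnostic_index] = baseline  # anchor exactly, no rounding drift
    flags = [
        "undefined" if t == 0 else ("not_detected" if c == 0 else "ok")
        for c, t in zip(counts, totals)
    ]
    return MrdSeries(
        clone=clone,
        sample_labels=list(table.sample_labels),
        counts=counts,
        totals=totals,
        abundance=abundance,
        scaled=scaled,
        baseline=float(baseline),
        flags=flags,
    )
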