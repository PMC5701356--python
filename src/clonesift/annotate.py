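"""Step 3 (germline assignment) — V/D/J annotation against an IMGT-style database.

Each putative clone is locally aligned against every germline segment of
each class (V-GENE, D-GENE, J-GENE).  Hits are ranked by an identity
measure — matched bases divided by all aligned columns (matches +
mismatches + gapped positions) — with the raw alignment score as
tiebreaker.  N positions never count as matches, so heavily N-masked
regions lower identity rather than inflating it.

The database is supplied by the user as FASTA; both the IMGT GENE-DB
pipe-separated header dialect (gene name in the second field) and plain
headers are accepted, with the class inferred from the fourth character
of the gene name (IGHV... -> V).  Following the VDJ architecture, the
short D segment is searched only between the best V and J alignments on
the clone when both exist, which suppresses spurious D hits inside the
V region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .align import sw_align
from .signature import ScoringParams

logger = logging.getLogger(__name__)

GENE_CLASSES = ("V", "D", "J")

__all__ = [
    "GermlineSegment",
    "GermlineHit",
    "VdjAnnotation",
    "load_germline",
    "annotate_clone",
]


@dataclass(frozen=True)
class GermlineSegment:
    gene_name: str
    gene_class: str  # one of V, D, J
    sequence: str

    def __post_init__(self):
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"gene_class must be one of {GENE_CLASSES}")
        if not self.sequence:
            raise ValueError("germline segment sequence must be non-empty")


@dataclass(frozen=True)
class GermlineHit:
    gene_name: str
    identity: float
    score: int


@dataclass
class VdjAnnotation:
    """Ranked best germline hits per class for one clone."""

    hits: dict = field(default_factory=dict)  # class -> [GermlineHit], ranked

    def best(self, gene_class: str) -> GermlineHit | None:
        ranked = self.hits.get(gene_class, [])
        return ranked[0] if ranked else None

    def identity(self, gene_class: str) -> float:
        hit = self.best(gene_class)
        return hit.identity if hit else 0.0


def _parse_header(description: str) -> tuple[str, str] | None:
    """(gene_name, gene_class) from a FASTA header, or None if unusable."""
    fields = description.split("|")
    name = fields[1].strip() if len(fields) >= 2 else fields[0].split()[0].strip()
    if len(name) >= 4 and name[3] in GENE_CLASSES:
        return name, name[3]
    return None


def load_germline(source) -> dict[str, list[GermlineSegment]]:
    """Parse a germline FASTA into segments grouped by class.

    *source* may be a path or an open text handle.  Headers that do not
    identify a V/D/J gene are skipped with a warning; an input providing
    no usable segment in some class is a hard error, since annotation
    needs all three classes.  Sequences are upper-cased and IMGT gap
    dots / dashes are stripped.
    """
    groups: dict[str, list[GermlineSegment]] = {c: [] for c in GENE_CLASSES}
    n_skipped = 0
    for record in SeqIO.parse(source, "fasta"):
        parsed = _parse_header(record.description)
        seq = str(record.seq).upper().replace(".", "").replace("-", "")
        if parsed is None or not seq:
            n_skipped += 1
            logger.warning("skipping unparseable germline record %r", record.description)
            continue
        name, cls = parsed
        groups[cls].append(GermlineSegment(name, cls, seq))
    if n_skipped:
        logger.warning("skipped %d unusable germline records", n_skipped)
    missing = [c for c in GENE_CLASSES if not groups[c]]
    if missing:
        found = {c: len(groups[c]) for c in GENE_CLASSES}
        raise ValueError(
            f"germline database lacks segments for class(es) {missing}; found {found}"
        )
    return groups


def _ranked_hits(
    query: str,
    segments: list[GermlineSegment],
    params: ScoringParams,
) -> tuple[list[GermlineHit], dict[str, tuple[int, int]]]:
    hits = []
    spans: dict[str, tuple[int, int]] = {}
    for seg in segments:
        stats = sw_align(query, seg.sequence, params.match, params.mismatch, params.indel)
        hits.append(GermlineHit(seg.gene_name, stats.identity, stats.score))
        spans[seg.gene_name] = (stats.a_start, stats.a_end)
    hits.sort(key=lambda h: (-h.identity, -h.score, h.gene_name))
    return hits, spans


def annotate_clone(
    clone_sequence: str,
    db: dict[str, list[GermlineSegment]],
    params: ScoringParams = ScoringParams(),
) -> VdjAnnotation:
    """Best V/D/J germline assignments for one clone sequence.

    V and J are searched over the whole clone; D is searched in the
    region between the best V and J alignments when that region is
    non-empty, otherwise over the whole clone.
    """
    if not clone_sequence:
        raise ValueError("clone sequence must be non-empty")
    for cls in GENE_CLASSES:
        if not db.get(cls):
            raise ValueError(f"germline database has no {cls} segments")
    clone_sequence = clone_sequence.upper()

    v_hits, v_spans = _ranked_hits(clone_sequence, db["V"], params)
    j_hits, j_spans = _ranked_hits(clone_sequence, db["J"], params)

    v_end = v_spans[v_hits[0].gene_name][1]
    j_start = j_spans[j_hits[0].gene_name][0]
    if 0 <= v_end < j_start <= len(clone_sequence):
        d_region = clone_sequence[v_end:j_start]
    else:
        d_region = clone_sequence
    if not d_region:
        d_region = clone_sequence
    d_hits, _ = _ranked_hits(d_region, db["D"], params)

    return VdjAnnotation(hits={"V": v_hits, "D": d_hits, "J": j_hits})
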