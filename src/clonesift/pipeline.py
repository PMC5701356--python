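"""End-to-end workflow: reads in, clone report and MRD series out.

Stages, mirroring the staged design of the method: per-sample k-mer
counting -> significant-k-mer selection over all samples -> per-sample
signature generation and similarity correction -> cross-sample clone
accumulation -> germline V/D/J annotation -> Phase-A / Phase-B
filtering -> major-clone selection and MRD quantification.

The major clone and its MRD series are taken from the Phase-A output:
Phase-B is an annotation-quality filter for the validated clone report,
and heavily N-masked data can push even the true clone's germline
identity below the homology cut without invalidating its frequency
trajectory, so MRD tracking must not depend on it.

Per-sample stages (signature generation + correction) are independent
and may run on a thread pool; results are collected in sample order, so
concurrent and sequential execution produce identical outputs.
"""

from __future__ import annotations

import gzip
import json
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .annotate import annotate_clone, load_germline
from .clone import CloneTable, accumulate_clones, frequency_matrix
from .filter_mrd import FilterConfig, MrdSeries, major_clone, mrd_series, phase_a, phase_b
from .kmer import SignificantKmerSet, find_significant_kmers
from .signature import ScoringParams, SignatureSet, collect_signatures, correct_signatures

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "read_sample", "write_clone_report"]


@dataclass
class RunConfig:
    """Everything one run needs; one sample must be flagged diagnostic."""

    samples: list  # ordered (label, path) pairs
    diagnostic: str  # label of the diagnostic sample
    germline: object  # path to a germline FASTA, or a pre-loaded group dict
    k: int = 25
    tau: float = 1.0
    scoring: ScoringParams = field(default_factory=ScoringParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    baseline: float = 1.0
    out_dir: Path | None = None
    seed: int = 0
    threads: int = 1

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("at least one sample is required")
        labels = [lab for lab, _ in self.samples]
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        if self.diagnostic not in labels:
            raise ValueError(
                f"diagnostic label {self.diagnostic!r} not among samples {labels}"
            )
        for _, path in self.samples:
            if not Path(path).exists():
                raise FileNotFoundError(path)
        if isinstance(self.germline, (str, Path)) and not Path(self.germline).exists():
            raise FileNotFoundError(self.germline)

    @property
    def diagnostic_index(self) -> int:
        return [lab for lab, _ in self.samples].index(self.diagnostic)


@dataclass
class PipelineResult:
    config: RunConfig
    psi: SignificantKmerSet
    signature_sets: list[SignatureSet]
    clone_table: CloneTable  # all accumulated clones, annotated
    phase_a_table: CloneTable
    phase_b_table: CloneTable
    major: object  # Clone or None when Phase-A is empty
    mrd: MrdSeries | None
    read_counts: list[int]
    skipped_reads: list[int]


def read_sample(path: str | Path) -> tuple[list[str], int]:
    """Load reads from FASTQ or FASTA, plain or gzipped.

    Quality lines are ignored.  Reads containing characters outside
    {A,C,G,T,N} are skipped with a warning; the skip count is returned.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        fh.seek(0)
        fmt = "fastq" if first == "@" else "fasta"
        reads, skipped = [], 0
        for rec in SeqIO.parse(fh, fmt):
            seq = str(rec.seq).upper()
            if set(seq) <= _VALID and seq:
                reads.append(seq)
            else:
                skipped += 1
                logger.warning("sample %s: skipping read %s with invalid characters",
                               path.name, rec.id)
    if skipped:
        logger.info("sample %s: skipped %d reads with non-ACGTN characters",
                    path.name, skipped)
    return reads, skipped


def _sign_one(reads, psi, index, scoring) -> SignatureSet:
    raw = collect_signatures(reads, psi, sample_index=index)
    return correct_signatures(raw, scoring)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow described in the module docstring."""
    config.validate()
    labels = [lab for lab, _ in config.samples]
    t0 = time.perf_counter()

    all_reads, skipped = [], []
    for lab, path in config.samples:
        reads, n_skipped = read_sample(path)
        if not reads:
            raise ValueError(f"sample {lab!r} ({path}) contains no usable reads")
        all_reads.append(reads)
        skipped.append(n_skipped)
        logger.info("stage=read sample=%s reads_in=%d skipped=%d", lab, len(reads), n_skipped)
    read_counts = [len(r) for r in all_reads]

    psi = find_significant_kmers(all_reads, config.k, config.tau)
    logger.info("stage=significant-kmers k=%d tau=%g kmers_out=%d",
                config.k, config.tau, len(psi))

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            futures = [
                pool.submit(_sign_one, reads, psi, i, config.scoring)
                for i, reads in enumerate(all_reads)
            ]
            signature_sets = [f.result() for f in futures]
    else:
        signature_sets = [
            _sign_one(reads, psi, i, config.scoring) for i, reads in enumerate(all_reads)
        ]
    for lab, sset in zip(labels, signature_sets):
        logger.info("stage=signatures sample=%s signatures_out=%d empty_reads=%d",
                    lab, len(sset), sset.n_empty_reads)

    table = accumulate_clones(
        signature_sets,
        config.scoring,
        sample_labels=labels,
        diagnostic_index=config.diagnostic_index,
        sample_totals=read_counts,
    )
    logger.info("stage=accumulate clones_out=%d", len(table))

    db = (
        config.germline
        if isinstance(config.germline, dict)
        else load_germline(config.germline)
    )
    for clone in table.clones:
        query = clone.exemplar_read or clone.sequence
        clone.annotation = annotate_clone(query, db, config.scoring)
    logger.info("stage=annotate clones=%d", len(table))

    a_table = phase_a(table, config.filters)
    b_table = phase_b(a_table, config.filters)
    logger.info("stage=filter phase_a=%d phase_b=%d", len(a_table), len(b_table))

    major = mrd = None
    if len(a_table):
        major = major_clone(a_table)
        mrd = mrd_series(major, a_table, config.baseline)
    else:
        logger.warning("no clone passed Phase-A; no MRD series produced")

    result = PipelineResult(
        config=config,
        psi=psi,
        signature_sets=signature_sets,
        clone_table=table,
        phase_a_table=a_table,
        phase_b_table=b_table,
        major=major,
        mrd=mrd,
        read_counts=read_counts,
        skipped_reads=skipped,
    )
    if config.out_dir is not None:
        _write_outputs(result)
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return result


# ---------------------------------------------------------------------------
# reporting


def _report_rows(table: CloneTable) -> list[dict]:
    rows = []
    ordered = sorted(
        table.clones,
        key=lambda c: (-int(c.freq_vector[table.diagnostic_index]), c.sequence),
    )
    for c in ordered:
        ann = c.annotation
        row = {
            "Signature": c.sequence,
            "Clone": c.exemplar_read or c.sequence,
        }
        for cls in ("V", "D", "J"):
            best = ann.best(cls) if ann else None
            row[f"{cls}-gene"] = best.gene_name if best else ""
            row[f"{cls}-identity"] = round(best.identity, 4) if best else ""
        for lab, f in zip(table.sample_labels, c.freq_vector):
            row[lab] = int(f)
        rows.append(row)
    return rows


def write_clone_report(table: CloneTable, path: str | Path, json_mirror: bool = True):
    """Write the data-grid TSV: Signature, Clone, V/D/J genes+identities,
    then one frequency column per sample.  A .json mirror is written
    next to it unless disabled."""
    path = Path(path)
    header = ["Signature", "Clone"]
    for cls in ("V", "D", "J"):
        header += [f"{cls}-gene", f"{cls}-identity"]
    header += list(table.sample_labels)
    rows = _report_rows(table)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[h]) for h in header) + "\n")
    if json_mirror:
        mirror = {
            "sample_labels": list(table.sample_labels),
            "diagnostic_index": table.diagnostic_index,
            "sample_totals": (
                [int(t) for t in table.sample_totals]
                if table.sample_totals is not None
                else None
            ),
            "clones": rows,
        }
        path.with_suffix(".json").write_text(json.dumps(mirror, indent=1))
    return path


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_clone_report(result.clone_table, out / "clones_all.tsv")
    write_clone_report(result.phase_b_table, out / "clones_filtered.tsv")
    frequency_matrix(result.clone_table).to_csv(out / "frequency_matrix.tsv", sep="\t")
    if result.mrd is not None:
        result.mrd.to_tsv(out / "mrd.tsv")
        (out / "mrd.json").write_text(json.dumps(result.mrd.to_dict(), indent=1))
    cfg = result.config
    manifest = {
        "samples": [[lab, str(p)] for lab, p in cfg.samples],
        "diagnostic": cfg.diagnostic,
        "k": cfg.k,
        "tau": cfg.tau,
        "scoring": cfg.scoring.__dict__,
        "filters": cfg.filters.__dict__,
        "baseline": cfg.baseline,
        "seed": cfg.seed,
        "threads": cfg.threads,
        "read_counts": result.read_counts,
        "skipped_reads": result.skipped_reads,
        "n_significant_kmers": len(result.psi),
        "n_clones": len(result.clone_table),
        "n_phase_a": len(result.phase_a_table),
        "n_phase_b": len(result.phase_b_table),
        "major_clone": result.major.sequence if result.major else None,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
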