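"""End-to-end pipeline: qc -> classify -> quantify, with a provenance manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .classify import AlignParams, SeedIndex, classify_reads
from .contamination import (
    UndefinedIndexError,
    contamination_index,
    table_report,
)
from .io import read_fasta, read_fastq, sha256_of, write_json
from .qc import (
    DEFAULT_MIN_SPAN,
    DEFAULT_SUBSAMPLE,
    DEFAULT_THRESHOLD_Q,
    optimal_read_span,
    position_quality_summary,
    subsample_reads,
    trim_reads_to_span,
)

logger = logging.getLogger("seracon")

__all__ = ["RunConfig", "run_pipeline", "load_samplesheet", "reference_from_fasta"]


@dataclass
class RunConfig:
    """Resolved parameters of a full pipeline run; fully serializable and
    echoed verbatim into the output manifest."""

    samplesheet: str
    ref_a: str
    ref_b: str
    out_dir: str
    threshold_q: float = DEFAULT_THRESHOLD_Q
    min_span: int = DEFAULT_MIN_SPAN
    subsample_n: int = DEFAULT_SUBSAMPLE
    trim: bool = True
    seed_length: int = 25
    seed_mismatches: int = 0
    min_score: int | None = None
    seed: int = 0
    numerator_group: str = "exosomal"
    denominator_group: str = "cellular"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_samplesheet(path: str | Path) -> pd.DataFrame:
    """Read a samplesheet TSV (sample_id, group, dataset, fastq)."""
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "group", "dataset"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"samplesheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in samplesheet: {dup!r}")
    return sheet


def reference_from_fasta(path: str | Path, spacer: int = 25) -> str:
    """Load a reference FASTA as a single sequence.

    Multiple records are concatenated with runs of N so seeds cannot span
    record boundaries.
    """
    seqs = read_fasta(path)
    if not seqs:
        raise ValueError(f"reference FASTA {path} contains no sequences")
    return ("N" * spacer).join(seqs.values())


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run qc -> classify -> quantify over a samplesheet.

    Datasets failing the min-span rule are discarded with a warning (not an
    error) and excluded from quantification, as are samples with an
    undefined contamination index. Returns the manifest dict (also written
    to out_dir/manifest.json).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = load_samplesheet(config.samplesheet)
    if "fastq" not in sheet.columns:
        raise ValueError("samplesheet must include a 'fastq' column for run_pipeline")

    params = AlignParams(
        seed_length=config.seed_length,
        seed_mismatches=config.seed_mismatches,
        min_score=config.min_score,
    )
    genome_a = reference_from_fasta(config.ref_a, spacer=config.seed_length)
    genome_b = reference_from_fasta(config.ref_b, spacer=config.seed_length)
    idx_a = SeedIndex(genome_a, params.seed_length)
    idx_b = SeedIndex(genome_b, params.seed_length)

    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "align_params": params.to_dict(),
        "inputs": {
            "ref_a": {"path": str(config.ref_a), "sha256": sha256_of(config.ref_a)},
            "ref_b": {"path": str(config.ref_b), "sha256": sha256_of(config.ref_b)},
            "samplesheet": {
                "path": str(config.samplesheet),
                "sha256": sha256_of(config.samplesheet),
            },
        },
        "samples": {},
        "outputs": {},
    }

    index_rows = []
    for _, row in sheet.iterrows():
        sid = row["sample_id"]
        entry: dict[str, Any] = {
            "fastq": {"path": row["fastq"], "sha256": sha256_of(row["fastq"])}
        }
        reads = read_fastq(row["fastq"])
        if not reads:
            entry["status"] = "discarded_empty"
            logger.warning("sample %s: empty FASTQ, discarded", sid)
            manifest["samples"][sid] = entry
            continue
        summary = position_quality_summary(reads)
        span = optimal_read_span(summary, config.threshold_q, config.min_span)
        span_path = out_dir / f"{sid}.span.json"
        write_json(span.to_dict(), span_path)
        entry["span"] = span.to_dict()
        entry["span_report"] = str(span_path)
        if not span.passed:
            entry["status"] = "discarded_span"
            logger.warning(
                "sample %s: optimal read span %d < %d bases, dataset discarded",
                sid, span.span_length, config.min_span,
            )
            manifest["samples"][sid] = entry
            continue
        if config.trim:
            reads = trim_reads_to_span(reads, span)
        reads = subsample_reads(reads, config.subsample_n, seed=config.seed)
        result = classify_reads(reads, idx_a, idx_b, params, sample_id=sid)
        cls_json = out_dir / f"{sid}.classification.json"
        write_json(result.to_dict(), cls_json)
        cls_tsv = out_dir / f"{sid}.categories.tsv"
        result.write_tsv(cls_tsv)
        entry["classification"] = str(cls_json)
        entry["categories"] = str(cls_tsv)
        try:
            idx = contamination_index(result)
        except UndefinedIndexError:
            entry["status"] = "excluded_undefined_index"
            logger.warning("sample %s: undefined contamination index, excluded", sid)
            manifest["samples"][sid] = entry
            continue
        entry["status"] = "ok"
        entry["index"] = idx.r
        manifest["samples"][sid] = entry
        index_rows.append(
            {"sample_id": sid, "dataset": row["dataset"], "group": row["group"],
             "index": idx.r}
        )

    if index_rows:
        indices = pd.DataFrame(index_rows)
        idx_path = out_dir / "indices.tsv"
        indices.to_csv(idx_path, sep="\t", index=False)
        manifest["outputs"]["indices"] = str(idx_path)
        have_both = {config.numerator_group, config.denominator_group} <= set(
            indices["group"]
        )
        if have_both:
            table, test = table_report(
                indices, config.numerator_group, config.denominator_group
            )
            table_path = out_dir / "report.tsv"
            with open(table_path, "w") as fh:
                fh.write(f"# seracon {__version__} seed={config.seed}\n")
                table.to_csv(fh, sep="\t", index=False)
            test_path = out_dir / "test.json"
            write_json(
                {"U": test.u, "p_two_tailed": test.p_two_tailed,
                 "method": test.method, "n_x": test.n_x, "n_y": test.n_y},
                test_path,
            )
            manifest["outputs"]["report"] = str(table_path)
            manifest["outputs"]["test"] = str(test_path)

    manifest_path = out_dir / "manifest.json"
    write_json(manifest, manifest_path)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
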