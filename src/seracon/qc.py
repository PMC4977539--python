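"""Read-quality gate.

Summarizes per-cycle quality over a FASTQ dataset, finds the longest
uninterrupted span of cycles whose aggregate quality strictly exceeds a
PHRED threshold (default 30), applies a minimum-span discard rule (default
20 bases), and provides span trimming and seeded uniform subsampling.
The span is a dataset-level property: one span, applied to all reads.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .io import Read, phred_values

__all__ = [
    "PositionQualitySummary",
    "SpanReport",
    "SpanFailError",
    "position_quality_summary",
    "optimal_read_span",
    "trim_reads_to_span",
    "subsample_reads",
    "DEFAULT_THRESHOLD_Q",
    "DEFAULT_MIN_SPAN",
    "DEFAULT_SUBSAMPLE",
]

DEFAULT_THRESHOLD_Q = 30.0
DEFAULT_MIN_SPAN = 20
DEFAULT_SUBSAMPLE = 1_000_000


class SpanFailError(ValueError):
    """Raised when an operation requires a passing span but got a failing one."""


@dataclass(frozen=True)
class PositionQualitySummary:
    """Aggregate PHRED quality per sequencing cycle.

    ``per_position_q[i]`` summarizes cycle i over all reads long enough to
    cover that cycle.
    """

    per_position_q: tuple[float, ...]
    n_reads_summarized: int
    statistic: str = "mean"

    def __len__(self) -> int:
        return len(self.per_position_q)


@dataclass(frozen=True)
class SpanReport:
    """The optimal read span and its pass/fail status.

    ``[start, end)`` is the longest maximal run of cycles whose summary
    quality strictly exceeds ``threshold_q``; the dataset fails (and is to
    be discarded) when the span is shorter than ``min_span``.
    """

    start: int
    end: int
    passed: bool
    threshold_q: float
    min_span: int
    n_reads: int

    @property
    def span_length(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        d = asdict(self)
        d["span_length"] = self.span_length
        return d


def position_quality_summary(
    reads: Sequence[Read], statistic: str = "mean"
) -> PositionQualitySummary:
    """Per-cycle quality summary over a read set.

    ``statistic`` is "mean" (default) or "median". Reads shorter than a
    given cycle simply do not contribute to it.
    """
    if len(reads) == 0:
        raise ValueError("cannot summarize an empty read set")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    max_len = max(len(r) for r in reads)
    if statistic == "mean":
        sums = np.zeros(max_len)
        counts = np.zeros(max_len, dtype=np.int64)
        for r in reads:
            q = np.frombuffer(r.qual.encode(), dtype=np.uint8).astype(np.int64) - 33
            sums[: len(q)] += q
            counts[: len(q)] += 1
        values = sums / counts
    else:
        per_cycle: list[list[int]] = [[] for _ in range(max_len)]
        for r in reads:
            for i, q in enumerate(phred_values(r.qual)):
                per_cycle[i].append(q)
        values = np.array([float(np.median(c)) for c in per_cycle])
    return PositionQualitySummary(
        per_position_q=tuple(float(v) for v in values),
        n_reads_summarized=len(reads),
        statistic=statistic,
    )


def optimal_read_span(
    summary: PositionQualitySummary,
    threshold_q: float = DEFAULT_THRESHOLD_Q,
    min_span: int = DEFAULT_MIN_SPAN,
) -> SpanReport:
    """Longest uninterrupted run of cycles with quality strictly > threshold.

    Ties between equal-length runs break to the smallest start (preserving
    5' sequence). A span shorter than ``min_span`` fails the gate.
    """
    if len(summary) == 0:
        raise ValueError("empty quality summary")
    best_start, best_len = 0, 0
    run_start: int | None = None
    q = summary.per_position_q
    for i in range(len(q) + 1):
        good = i < len(q) and q[i] > threshold_q
        if good and run_start is None:
            run_start = i
        elif not good and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    return SpanReport(
        start=best_start,
        end=best_start + best_len,
        passed=best_len >= min_span,
        threshold_q=threshold_q,
        min_span=min_span,
        n_reads=summary.n_reads_summarized,
    )


def trim_reads_to_span(reads: Sequence[Read], span: SpanReport) -> list[Read]:
    """Slice every read to the span interval.

    Reads whose remaining slice is shorter than ``span.min_span`` are
    dropped. Refuses to trim with a failing span.
    """
    if not span.passed:
        raise SpanFailError(
            f"span [{span.start}, {span.end}) of length {span.span_length} "
            f"fails the min_span={span.min_span} rule; dataset should be discarded"
        )
    out: list[Read] = []
    for r in reads:
        seq = r.seq[span.start : span.end]
        if len(seq) < span.min_span:
            continue
        out.append(Read(r.id, seq, r.qual[span.start : span.end]))
    return out


def subsample_reads(
    reads: Sequence[Read], n: int = DEFAULT_SUBSAMPLE, seed: int = 0
) -> list[Read]:
    """Uniform sample of min(n, len(reads)) reads without replacement.

    Deterministic under ``seed``; output preserves input-file order.
    """
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    if n >= len(reads):
        return list(reads)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.choice(len(reads), size=n, replace=False)
    idx.sort()
    return [reads[i] for i in idx]
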