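"""Competitive read classification against two reference genomes.

Each read is aligned independently to genome A and genome B and placed in
exactly one of four categories: specific-A (aligns to A only), specific-B
(aligns to B only), both, or neither. Species-specific categories feed the
contamination index downstream.

The built-in aligner is seed-and-extend, local and ungapped: a read maps to
a genome iff some ungapped local segment (match +2 / mismatch -4) contains
an exact ``seed_length``-mer shared with the genome and scores at least
``min_score``. With the default ``min_score = 2 * seed_length`` a perfect
seed alone suffices to call "mapped". Gapped alignment is available only by
ingesting external SAM files (:func:`classify_from_alignments`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Read, read_sam_mapped
from .simulate import revcomp

__all__ = [
    "AlignParams",
    "AlignmentHit",
    "ClassificationResult",
    "SeedIndex",
    "ConsistencyError",
    "build_index",
    "align_read",
    "classify_reads",
    "classify_from_alignments",
    "CATEGORIES",
]

CATEGORIES = ("specific_a", "specific_b", "both", "neither")

_ACGT = frozenset(b"ACGT")


class ConsistencyError(ValueError):
    """Paired alignment files disagree on the read-id universe."""


@dataclass(frozen=True)
class AlignParams:
    """Alignment parameters for the built-in local aligner.

    ``seed_length`` is the exact-match seed width (default 25) and
    ``seed_mismatches`` the number of mismatches tolerated inside the seed
    (0 or 1, default 0). ``min_score`` defaults to ``2 * seed_length``.
    """

    seed_length: int = 25
    seed_mismatches: int = 0
    match: int = 2
    mismatch: int = -4
    min_score: int | None = None
    search_both_strands: bool = True
    mode: str = "local"

    def __post_init__(self) -> None:
        if self.seed_length < 10:
            raise ValueError(f"seed_length must be >= 10, got {self.seed_length}")
        if self.seed_mismatches not in (0, 1):
            raise ValueError("seed_mismatches must be 0 or 1")
        if self.mode != "local":
            raise ValueError("only local mode is supported")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")
        if self.resolved_min_score <= 0:
            raise ValueError("min_score must be positive")

    @property
    def resolved_min_score(self) -> int:
        return self.min_score if self.min_score is not None else 2 * self.seed_length

    def to_dict(self) -> dict:
        return {
            "seed_length": self.seed_length,
            "seed_mismatches": self.seed_mismatches,
            "match": self.match,
            "mismatch": self.mismatch,
            "min_score": self.resolved_min_score,
            "search_both_strands": self.search_both_strands,
            "mode": self.mode,
        }


@dataclass(frozen=True)
class AlignmentHit:
    """Best local hit of one read on one genome (forward-strand coords)."""

    read_id: str | None
    genome: str
    start: int
    end: int
    strand: str
    score: int

    @property
    def aligned_length(self) -> int:
        return self.end - self.start


class SeedIndex:
    """Exact-match lookup from every ``seed_length``-mer of a genome to its
    forward-strand positions. K-mers containing ambiguous bases produce no
    seeds. Minus-strand hits are found by querying the reverse complement
    of the read, so only the forward strand is stored."""

    def __init__(self, genome: str, seed_length: int = 25):
        genome = genome.upper()
        if len(genome) < seed_length:
            raise ValueError(
                f"genome length {len(genome)} is shorter than seed_length "
                f"{seed_length}"
            )
        self.genome = genome
        self.seed_length = seed_length
        arr = np.frombuffer(genome.encode(), dtype=np.uint8)
        valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        # A k-mer window is indexable iff all its bases are unambiguous.
        win_ok = (
            np.convolve(valid.astype(np.int32), np.ones(seed_length, dtype=np.int32),
                        mode="valid")
            == seed_length
        )
        index: dict[str, list[int]] = {}
        for p in np.nonzero(win_ok)[0]:
            kmer = genome[p : p + seed_length]
            index.setdefault(kmer, []).append(int(p))
        self._index = index

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._index

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, kmer: str) -> tuple[int, ...]:
        return tuple(self._index.get(kmer, ()))


def build_index(genome: str, seed_length: int = 25) -> SeedIndex:
    """Build a :class:`SeedIndex` over a genome."""
    return SeedIndex(genome, seed_length)


def _one_mismatch_variants(kmer: str) -> Iterable[str]:
    for i, c in enumerate(kmer):
        for b in "ACGT":
            if b != c:
                yield kmer[:i] + b + kmer[i + 1 :]


def _extend_window(
    scores: Sequence[int], w_start: int, w_end: int
) -> tuple[int, int, int]:
    """Best-scoring segment constrained to contain [w_start, w_end).

    Returns (score, a, b) for segment [a, b); extensions keep the shortest
    interval achieving the maximum (strict improvement only).
    """
    total = sum(scores[w_start:w_end])
    best_l, best_a, s = 0, w_start, 0
    for a in range(w_start - 1, -1, -1):
        s += scores[a]
        if s > best_l:
            best_l, best_a = s, a
    best_r, best_b, s = 0, w_end, 0
    for b in range(w_end, len(scores)):
        s += scores[b]
        if s > best_r:
            best_r, best_b = s, b + 1
    return total + best_l + best_r, best_a, best_b


def _seed_hits(seq: str, index: SeedIndex, params: AlignParams):
    """Yield (read_offset, genome_position, n_seed_mismatches) seed hits."""
    L = index.seed_length
    for o in range(len(seq) - L + 1):
        kmer = seq[o : o + L]
        for p in index.lookup(kmer):
            yield o, p, 0
        if params.seed_mismatches == 1:
            for variant in _one_mismatch_variants(kmer):
                for p in index.lookup(variant):
                    yield o, p, 1


def align_read(
    read: str | Read,
    index: SeedIndex,
    params: AlignParams | None = None,
    genome_label: str = "A",
) -> AlignmentHit | None:
    """Best local hit of a read on an indexed genome, or None.

    Seed hits are extended ungapped in both directions keeping the best
    local segment containing the seed window. The reported hit is the
    highest-scoring one with score >= min_score; ties break to the lowest
    forward-strand genome position, then to the '+' strand. A read shorter
    than the seed length cannot seed and is reported unmapped (None).
    """
    params = params or AlignParams(seed_length=index.seed_length)
    if params.seed_length != index.seed_length:
        raise ValueError("params.seed_length does not match the index")
    read_id = read.id if isinstance(read, Read) else None
    seq = (read.seq if isinstance(read, Read) else read).upper()
    genome = index.genome
    strands = [("+", seq)]
    if params.search_both_strands:
        strands.append(("-", revcomp(seq)))

    best: tuple[int, int, int, AlignmentHit] | None = None  # sort key + hit
    for strand_rank, (strand, s) in enumerate(strands):
        seen: set[tuple[int, int]] = set()
        for o, p, _mm in _seed_hits(s, index, params):
            diag = p - o  # genome coordinate aligned to read position 0
            if (diag, o) in seen:
                continue
            seen.add((diag, o))
            i0 = max(0, -diag)
            i1 = min(len(s), len(genome) - diag)
            scores = [
                params.match if s[i] == genome[diag + i] else params.mismatch
                for i in range(i0, i1)
            ]
            score, a, b = _extend_window(scores, o - i0, o + index.seed_length - i0)
            g_start = diag + i0 + a
            g_end = diag + i0 + b
            key = (-score, g_start, strand_rank)
            if best is None or key < best[:3]:
                best = (
                    *key,
                    AlignmentHit(
                        read_id=read_id,
                        genome=genome_label,
                        start=g_start,
                        end=g_end,
                        strand=strand,
                        score=score,
                    ),
                )
    if best is None or best[3].score < params.resolved_min_score:
        return None
    return best[3]


@dataclass
class ClassificationResult:
    """Per-read categories and aggregate counts for one sample."""

    per_read_category: dict[str, str]
    params: AlignParams | None = None
    sample_id: str | None = None

    @property
    def n_specific_a(self) -> int:
        return sum(1 for c in self.per_read_category.values() if c == "specific_a")

    @property
    def n_specific_b(self) -> int:
        return sum(1 for c in self.per_read_category.values() if c == "specific_b")

    @property
    def n_both(self) -> int:
        return sum(1 for c in self.per_read_category.values() if c == "both")

    @property
    def n_neither(self) -> int:
        return sum(1 for c in self.per_read_category.values() if c == "neither")

    @property
    def total(self) -> int:
        return len(self.per_read_category)

    def counts(self) -> dict[str, int]:
        out = dict.fromkeys(CATEGORIES, 0)
        for c in self.per_read_category.values():
            out[c] += 1
        return out

    def to_dict(self) -> dict:
        d: dict = {"sample_id": self.sample_id, "total": self.total}
        d.update({f"n_{k}": v for k, v in self.counts().items()})
        if self.params is not None:
            d["params"] = self.params.to_dict()
        return d

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tcategory\n")
            for rid, cat in self.per_read_category.items():
                fh.write(f"{rid}\t{cat}\n")


def _category(mapped_a: bool, mapped_b: bool) -> str:
    if mapped_a and mapped_b:
        return "both"
    if mapped_a:
        return "specific_a"
    if mapped_b:
        return "specific_b"
    return "neither"


def _maps_by_seed(seq: str, index: SeedIndex, both_strands: bool) -> bool:
    """Mapped check valid when any exact seed already meets min_score."""
    L = index.seed_length
    queries = [seq] if not both_strands else [seq, revcomp(seq)]
    for s in queries:
        for o in range(len(s) - L + 1):
            if s[o : o + L] in index:
                return True
    return False


def classify_reads(
    reads: Sequence[Read | str] | Iterable[Read | str],
    genome_a: str | SeedIndex,
    genome_b: str | SeedIndex,
    params: AlignParams | None = None,
    sample_id: str | None = None,
) -> ClassificationResult:
    """Competitively classify reads against two genomes.

    Any hit meeting ``min_score`` in a genome marks the read as mapped to
    it, regardless of multi-mapping within that genome. An empty read set
    yields an empty result with zero counts.
    """
    params = params or AlignParams()
    idx_a = genome_a if isinstance(genome_a, SeedIndex) else SeedIndex(genome_a, params.seed_length)
    idx_b = genome_b if isinstance(genome_b, SeedIndex) else SeedIndex(genome_b, params.seed_length)
    if idx_a.seed_length != params.seed_length or idx_b.seed_length != params.seed_length:
        raise ValueError("both genomes must be indexed with params.seed_length")

    # When a bare exact seed already reaches min_score, mapping reduces to
    # shared-k-mer membership and extension can be skipped entirely.
    fast = (
        params.seed_mismatches == 0
        and params.resolved_min_score <= params.match * params.seed_length
    )
    categories: dict[str, str] = {}
    for i, read in enumerate(reads):
        rid = read.id if isinstance(read, Read) else f"read{i}"
        seq = (read.seq if isinstance(read, Read) else read).upper()
        if fast:
            mapped_a = _maps_by_seed(seq, idx_a, params.search_both_strands)
            mapped_b = _maps_by_seed(seq, idx_b, params.search_both_strands)
        else:
            mapped_a = align_read(seq, idx_a, params, "A") is not None
            mapped_b = align_read(seq, idx_b, params, "B") is not None
        categories[rid] = _category(mapped_a, mapped_b)
    return ClassificationResult(per_read_category=categories, params=params,
                                sample_id=sample_id)


def classify_from_alignments(
    sam_a: str | Path, sam_b: str | Path, sample_id: str | None = None
) -> ClassificationResult:
    """Classify reads from two external SAM files (one per genome).

    Both files must cover the same read-id set; mapped status is read from
    flag bit 0x4 of primary records only.
    """
    status_a = read_sam_mapped(sam_a)
    status_b = read_sam_mapped(sam_b)
    only_a = sorted(set(status_a) - set(status_b))
    only_b = sorted(set(status_b) - set(status_a))
    if only_a or only_b:
        example = (only_a or only_b)[0]
        raise ConsistencyError(
            f"read id {example!r} present in only one alignment file "
            f"({len(only_a)} ids only in A, {len(only_b)} only in B)"
        )
    categories = {
        rid: _category(status_a[rid], status_b[rid]) for rid in status_a
    }
    return ClassificationResult(per_read_category=categories, params=None,
                                sample_id=sample_id)
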