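"""Exhaustive reference implementation of the alignment contract.

Independent of the seed index: for every diagonal of the full (read x
genome) comparison matrix, on both strands, this finds the best ungapped
local segment that contains an exact run of ``seed_length`` matches, by
brute-force enumeration over all segment boundaries. It exists solely to
cross-check :mod:`seracon.classify`; it shares no alignment code with it.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .classify import AlignParams, AlignmentHit, _category
from .io import Read
from .simulate import revcomp

__all__ = ["oracle_best_hit", "oracle_classify"]

# Distinct sentinel codes so that ambiguous bases and out-of-genome padding
# can never produce a match.
_READ_TABLE = np.full(256, 100, dtype=np.uint8)
_GENOME_TABLE = np.full(256, 200, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _READ_TABLE[_b] = _i
    _GENOME_TABLE[_b] = _i
_PAD = 255


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _match_matrix(read_codes: np.ndarray, genome_codes: np.ndarray) -> np.ndarray:
    """Boolean matrix M[d, i]: read base i matches genome base (d - Lr + i),
    where d indexes diagonals of the padded genome."""
    lr = read_codes.size
    padded = np.concatenate(
        [np.full(lr, _PAD, np.uint8), genome_codes, np.full(lr, _PAD, np.uint8)]
    )
    windows = sliding_window_view(padded, lr)
    return windows == read_codes


def _seeded_diagonals(m: np.ndarray, seed_length: int) -> np.ndarray:
    """Indices of diagonals containing a run of >= seed_length matches."""
    run = np.zeros(m.shape[0], dtype=np.int32)
    max_run = np.zeros_like(run)
    for i in range(m.shape[1]):
        run = (run + 1) * m[:, i]
        np.maximum(max_run, run, out=max_run)
    return np.nonzero(max_run >= seed_length)[0]


def _best_segment_with_seed(
    matches: np.ndarray, params: AlignParams
) -> tuple[int, int, int] | None:
    """Best (score, a, b) over all segments [a, b) that contain an exact
    match run of >= seed_length, by full enumeration. Ties prefer the
    largest a, then the smallest b."""
    lr = matches.size
    scores = np.where(matches, params.match, params.mismatch).astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(scores)])

    # Maximal match runs.
    runs: list[tuple[int, int]] = []
    i = 0
    while i < lr:
        if matches[i]:
            j = i
            while j < lr and matches[j]:
                j += 1
            if j - i >= params.seed_length:
                runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return None

    best: tuple[int, int, int] | None = None
    for rs, re in runs:
        for a in range(rs, -1, -1):
            for b in range(re, lr + 1):
                score = int(prefix[b] - prefix[a])
                if best is None or score > best[0]:
                    best = (score, a, b)
    return best


def oracle_best_hit(
    read: str | Read,
    genome: str,
    params: AlignParams | None = None,
    genome_label: str = "A",
) -> AlignmentHit | None:
    """Exhaustively computed best hit under the classify-module contract."""
    params = params or AlignParams()
    if params.seed_mismatches != 0:
        raise NotImplementedError("oracle supports exact seeds only")
    read_id = read.id if isinstance(read, Read) else None
    seq = read.seq if isinstance(read, Read) else read
    lr = len(seq)
    gcodes = _encode(genome, _GENOME_TABLE)

    strands = [("+", seq)]
    if params.search_both_strands:
        strands.append(("-", revcomp(seq)))

    best: tuple[int, int, int, AlignmentHit] | None = None
    for strand_rank, (strand, s) in enumerate(strands):
        rcodes = _encode(s, _READ_TABLE)
        m = _match_matrix(rcodes, gcodes)
        for d in _seeded_diagonals(m, params.seed_length):
            seg = _best_segment_with_seed(m[d], params)
            if seg is None:
                continue
            score, a, b = seg
            g_start = int(d) - lr + a
            g_end = int(d) - lr + b
            key = (-score, g_start, strand_rank)
            if best is None or key < best[:3]:
                best = (
                    *key,
                    AlignmentHit(read_id=read_id, genome=genome_label,
                                 start=g_start, end=g_end, strand=strand,
                                 score=score),
                )
    if best is None or best[3].score < params.resolved_min_score:
        return None
    return best[3]


def _oracle_maps(seq: str, gcodes: np.ndarray, params: AlignParams) -> bool:
    lr = len(seq)
    strands = [seq]
    if params.search_both_strands:
        strands.append(revcomp(seq))
    shortcut = params.resolved_min_score <= params.match * params.seed_length
    for s in strands:
        m = _match_matrix(_encode(s, _READ_TABLE), gcodes)
        diags = _seeded_diagonals(m, params.seed_length)
        if diags.size == 0:
            continue
        if shortcut:
            return True
        for d in diags:
            seg = _best_segment_with_seed(m[d], params)
            if seg is not None and seg[0] >= params.resolved_min_score:
                return True
    return False


def oracle_classify(
    reads,
    genome_a: str,
    genome_b: str,
    params: AlignParams | None = None,
) -> dict[str, str]:
    """Per-read categories computed by exhaustive diagonal enumeration."""
    params = params or AlignParams()
    if params.seed_mismatches != 0:
        raise NotImplementedError("oracle supports exact seeds only")
    ga = _encode(genome_a, _GENOME_TABLE)
    gb = _encode(genome_b, _GENOME_TABLE)
    out: dict[str, str] = {}
    for i, read in enumerate(reads):
        rid = read.id if isinstance(read, Read) else f"read{i}"
        seq = (read.seq if isinstance(read, Read) else read).upper()
        out[rid] = _category(
            _oracle_maps(seq, ga, params), _oracle_maps(seq, gb, params)
        )
    return out
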