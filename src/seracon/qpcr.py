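"""qPCR analytics: delta-Cq quantification and geNorm normalization.

Cq tables are samples x genes. Relative quantities assume a per-gene
amplification efficiency E (default 2.0, perfect doubling). geNorm
stability M for a gene is the mean, over all other candidate genes, of the
standard deviation across samples of the pairwise log2 quantity ratios;
lower M means more stable. Normalization factors are per-sample geometric
means of the control-gene quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenormResult",
    "relative_quantity",
    "cq_to_relative_quantity",
    "genorm_m_values",
    "genorm_ranking",
    "genorm_normalization_factor",
    "normalize_expression",
    "CQ_CEILING",
]

#: Undetermined / no-amplification wells are encoded at this Cq ceiling.
CQ_CEILING = 40.0


def relative_quantity(
    cq_target: float, cq_reference: float, efficiency: float = 2.0
) -> float:
    """RQ = E^(Cq_reference - Cq_target)."""
    if efficiency <= 1:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    if not (np.isfinite(cq_target) and np.isfinite(cq_reference)):
        raise ValueError("Cq values must be finite")
    return float(efficiency ** (cq_reference - cq_target))


def cq_to_relative_quantity(cq: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per-gene relative quantities E^(min_Cq - Cq); the most abundant
    sample of each gene gets quantity 1."""
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    return efficiency ** (cq.min(axis=0) - cq)


def _check_table(cq: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    missing = [g for g in genes if g not in cq.columns]
    if missing:
        raise ValueError(f"genes absent from Cq table: {missing}")
    if cq.shape[0] < 2:
        raise ValueError("at least 2 samples are required")
    return cq[list(genes)]


@dataclass
class GenormResult:
    m_values: pd.Series
    normalization_factor: pd.Series | None = None


def genorm_m_values(
    cq: pd.DataFrame,
    candidate_genes: Sequence[str] | None = None,
    efficiency: float = 2.0,
) -> pd.Series:
    """geNorm stability M per candidate gene (lower is more stable)."""
    genes = list(candidate_genes) if candidate_genes is not None else list(cq.columns)
    if len(genes) < 2:
        raise ValueError("geNorm needs at least 2 candidate genes")
    sub = _check_table(cq, genes)
    q = cq_to_relative_quantity(sub, efficiency)
    logq = np.log2(q)
    m = {}
    for g in genes:
        sds = [
            float((logq[g] - logq[h]).std(ddof=1)) for h in genes if h != g
        ]
        m[g] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_ranking(
    cq: pd.DataFrame,
    candidate_genes: Sequence[str] | None = None,
    efficiency: float = 2.0,
) -> list[tuple[str, float]]:
    """Iterative geNorm ranking: repeatedly drop the least-stable gene.

    Returns (gene, M at elimination) from least to most stable; the final
    two genes cannot be ranked apart and share the last M.
    """
    genes = list(candidate_genes) if candidate_genes is not None else list(cq.columns)
    if len(genes) < 2:
        raise ValueError("geNorm needs at least 2 candidate genes")
    remaining = list(genes)
    out: list[tuple[str, float]] = []
    while len(remaining) > 2:
        m = genorm_m_values(cq, remaining, efficiency)
        worst = m.sort_values(ascending=False, kind="stable").index[0]
        out.append((worst, float(m[worst])))
        remaining.remove(worst)
    m = genorm_m_values(cq, remaining, efficiency)
    out.extend((g, float(m[g])) for g in remaining)
    return out


def genorm_normalization_factor(
    cq: pd.DataFrame,
    control_genes: Sequence[str],
    efficiency: float = 2.0,
) -> pd.Series:
    """Per-sample geometric mean of the control genes' relative quantities.

    Samples with a missing control Cq are excluded with a warning.
    """
    controls = list(control_genes)
    if len(controls) < 2:
        raise ValueError("at least 2 control genes are required")
    sub = _check_table(cq, controls)
    incomplete = sub.index[sub.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"sample(s) missing control Cq values excluded: {list(incomplete)}",
            stacklevel=2,
        )
        sub = sub.drop(index=incomplete)
    q = cq_to_relative_quantity(sub, efficiency)
    factor = np.exp(np.log(q).mean(axis=1))
    factor.name = "normalization_factor"
    return factor


def normalize_expression(
    cq: pd.DataFrame,
    control_genes: Sequence[str],
    target_genes: Sequence[str] | None = None,
    efficiency: float = 2.0,
    cq_ceiling: float = CQ_CEILING,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """geNorm-normalized relative quantities for target genes.

    Returns (normalized RQ, undetected flags); a well is flagged
    undetected when its raw Cq is at or above ``cq_ceiling`` (the
    no-amplification encoding).
    """
    controls = list(control_genes)
    targets = (
        list(target_genes)
        if target_genes is not None
        else [g for g in cq.columns if g not in controls]
    )
    if not targets:
        raise ValueError("no target genes to normalize")
    factor = genorm_normalization_factor(cq, controls, efficiency)
    sub = _check_table(cq, targets).loc[factor.index]
    rq = cq_to_relative_quantity(sub, efficiency)
    normalized = rq.div(factor, axis=0)
    undetected = sub >= cq_ceiling
    return normalized, undetected
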