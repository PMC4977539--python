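"""RNA composition analytics.

Reads-per-million normalization of biotype count tables, composition
summaries with group mean +/- SEM, top-k feature ranking,
pellet/supernatant depletion efficiency, and average-linkage hierarchical
clustering of samples on Pearson-correlation distance of log-transformed
profiles. Consumes pre-annotated count tables; read-to-biotype annotation
is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "BiotypeCountTable",
    "ClusterTree",
    "rpm_normalize",
    "biotype_composition",
    "top_k_features",
    "depletion_efficiency",
    "depletion_efficiency_from_cq",
    "percent_removed",
    "pearson_cluster",
    "RPM_SCALE",
]

RPM_SCALE = 1_000_000

KNOWN_BIOTYPES = ("miRNA", "mRNA", "rRNA", "snoRNA", "antisense", "Y RNA", "other")


@dataclass
class BiotypeCountTable:
    """Samples x features mapped-read counts plus annotations.

    ``biotypes`` maps each feature to its biotype; ``sample_groups`` maps
    each sample to its group/fraction label (e.g. pellet vs supernatant).
    """

    counts: pd.DataFrame
    biotypes: pd.Series
    sample_groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def features(self) -> list[str]:
        return list(self.counts.columns)


def rpm_normalize(table: BiotypeCountTable | pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (row) to reads per million mapped.

    Raises on any zero-total sample, naming it.
    """
    counts = table.counts if isinstance(table, BiotypeCountTable) else table
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero mapped reads cannot be normalized: "
            f"{list(zero.index)}"
        )
    return counts.div(totals, axis=0) * RPM_SCALE


def _group_mean_sem(frac: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    rows = []
    for g, sub in frac.groupby(groups, sort=True):
        mean = sub.mean(axis=0)
        sem = sub.std(axis=0, ddof=1) / np.sqrt(len(sub)) if len(sub) > 1 else None
        for col in frac.columns:
            rows.append({
                "group": g,
                "biotype": col,
                "mean": float(mean[col]),
                "sem": float(sem[col]) if sem is not None else float("nan"),
                "n": len(sub),
            })
    return pd.DataFrame(rows)


def biotype_composition(
    rpm: pd.DataFrame,
    biotypes: pd.Series,
    sample_groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample biotype fractions (and group mean +/- SEM if grouped).

    Features missing an annotation are assigned "other" with a warning.
    """
    anno = biotypes.reindex(rpm.columns)
    unannotated = anno[anno.isna()].index
    if len(unannotated):
        warnings.warn(
            f"{len(unannotated)} unannotated feature(s) assigned biotype "
            f"'other': {list(unannotated)[:5]}",
            stacklevel=2,
        )
        anno = anno.fillna("other")
    sums = rpm.T.groupby(anno.values).sum().T
    fractions = sums.div(sums.sum(axis=1), axis=0)
    summary = None
    if sample_groups is not None:
        summary = _group_mean_sem(fractions, sample_groups.reindex(fractions.index))
    return fractions, summary


def top_k_features(
    rpm: pd.DataFrame,
    biotypes: pd.Series,
    biotype: str,
    k: int,
    sample_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Top-k features of one biotype ranked by overall mean RPM.

    Ties break alphabetically by feature name. If k exceeds the number of
    features of that biotype, all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    feats = [f for f in rpm.columns if biotypes.get(f) == biotype]
    if not feats:
        raise ValueError(f"no features with biotype {biotype!r}")
    sub = rpm[feats]
    means = sub.mean(axis=0)
    ranked = sorted(means.index, key=lambda f: (-means[f], f))[:k]
    out = pd.DataFrame(
        {"feature": ranked, "mean_rpm": [float(means[f]) for f in ranked]}
    )
    if sample_groups is not None:
        for g, samples in sample_groups.groupby(sample_groups):
            out[f"mean_rpm_{g}"] = [
                float(sub.loc[samples.index, f].mean()) for f in out["feature"]
            ]
    return out


def depletion_efficiency(pellet_abundance: float, supernatant_abundance: float) -> float:
    """Pellet/supernatant abundance ratio; > 1 means efficient pelleting."""
    if pellet_abundance <= 0 or supernatant_abundance <= 0:
        raise ValueError("abundances must be positive")
    return pellet_abundance / supernatant_abundance


def depletion_efficiency_from_cq(
    cq_pellet: float, cq_supernatant: float, efficiency: float = 2.0
) -> float:
    """Depletion efficiency from Cq values: E^(Cq_supernatant - Cq_pellet)."""
    if not (np.isfinite(cq_pellet) and np.isfinite(cq_supernatant)):
        raise ValueError("Cq values must be finite")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    return float(efficiency ** (cq_supernatant - cq_pellet))


def percent_removed(pellet_mass: float, supernatant_mass: float) -> float:
    """Percent of total mass recovered in the pellet fraction."""
    if pellet_mass < 0 or supernatant_mass < 0:
        raise ValueError("masses must be non-negative")
    total = pellet_mass + supernatant_mass
    if total == 0:
        raise ValueError("total mass is zero")
    return 100.0 * pellet_mass / total


@dataclass
class ClusterTree:
    """Sample dendrogram from average-linkage Pearson-distance clustering."""

    linkage_matrix: np.ndarray
    labels: list[str]
    pseudocount: float
    log_base: float
    linkage_method: str

    def cut(self, k: int) -> dict[str, int]:
        """Assign samples to k flat clusters (top k-1 merges removed)."""
        flat = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return {s: int(c) for s, c in zip(self.labels, flat)}

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.get_left(), node.dist)
            right = fmt(node.get_right(), node.dist)
            return f"({left},{right}):{length:.6g}"

        left = fmt(root.get_left(), root.dist)
        right = fmt(root.get_right(), root.dist)
        return f"({left},{right});"


def pearson_cluster(
    rpm: pd.DataFrame,
    pseudocount: float = 1.0,
    log_base: float = 10.0,
    linkage: str = "average",
) -> ClusterTree:
    """Cluster samples on 1 - Pearson r of log(RPM + pseudocount) profiles.

    Agglomerative with average linkage by default (single/complete
    available). Raises on samples with zero-variance log profiles, for
    which Pearson correlation is undefined.
    """
    if rpm.shape[0] < 2 or rpm.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    logged = np.log(rpm.values + pseudocount) / np.log(log_base)
    flat = logged.std(axis=1) == 0
    if flat.any():
        bad = list(rpm.index[flat])
        raise ValueError(
            f"zero-variance profile(s), Pearson distance undefined: {bad}"
        )
    dist = pdist(logged, metric="correlation")
    z = hierarchy.linkage(dist, method=linkage)
    return ClusterTree(
        linkage_matrix=z,
        labels=list(rpm.index),
        pseudocount=pseudocount,
        log_base=log_base,
        linkage_method=linkage,
    )
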