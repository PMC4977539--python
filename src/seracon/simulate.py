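"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes: a pair of genomes related by a
controlled substitution divergence, single-end read mixtures drawn from the
two genomes at a known contamination fraction, grouped biotype count tables
and qPCR Cq tables. One top-level seed is split hierarchically so every
artifact is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Read, write_fasta, write_fastq

__all__ = [
    "GenomePair",
    "MixtureConfig",
    "LabeledReadSet",
    "evolve_genome_pair",
    "simulate_reads",
    "simulate_count_table",
    "simulate_cq_table",
    "revcomp",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MIN_GENOME_LENGTH = 1000


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomePair:
    """Two equal-length genomes related by i.i.d. substitutions.

    ``seq_a`` plays the host (human-analog) role, ``seq_b`` the contaminant
    (bovine-analog) role.
    """

    seq_a: str
    seq_b: str
    divergence: float
    seed: int

    @property
    def length(self) -> int:
        return len(self.seq_a)

    def observed_divergence(self) -> float:
        """Realized per-site mismatch fraction between the two genomes."""
        a = np.frombuffer(self.seq_a.encode(), dtype=np.uint8)
        b = np.frombuffer(self.seq_b.encode(), dtype=np.uint8)
        return float(np.mean(a != b))

    def write(self, path: str | Path) -> None:
        write_fasta({"genome_a": self.seq_a, "genome_b": self.seq_b}, path)


def evolve_genome_pair(length: int, divergence: float, seed: int = 0) -> GenomePair:
    """Draw a random ancestral sequence and a diverged copy.

    Each position of the copy is substituted with probability ``divergence``
    to a uniformly chosen *different* base.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    if length < MIN_GENOME_LENGTH:
        raise ValueError(
            f"genome length must be >= {MIN_GENOME_LENGTH}, got {length}"
        )
    root, branch = np.random.SeedSequence(seed).spawn(2)
    rng_root = np.random.default_rng(root)
    rng_branch = np.random.default_rng(branch)

    codes_a = rng_root.integers(0, 4, size=length)
    mask = rng_branch.random(length) < divergence
    # Substitute to one of the 3 other bases, uniformly.
    shift = rng_branch.integers(1, 4, size=length)
    codes_b = np.where(mask, (codes_a + shift) % 4, codes_a)

    seq_a = _BASES[codes_a].tobytes().decode()
    seq_b = _BASES[codes_b].tobytes().decode()
    return GenomePair(seq_a=seq_a, seq_b=seq_b, divergence=divergence, seed=seed)


@dataclass(frozen=True)
class MixtureConfig:
    """Parameters of a two-species read mixture.

    ``contamination_fraction`` is the probability that a read originates
    from genome B — the ground-truth value the downstream contamination
    index estimates.
    """

    n_reads: int
    contamination_fraction: float
    read_length: int = 50
    error_rate: float = 0.0
    quality_model: tuple[float, ...] = (38.0, 32.0)
    seed: int = 0

    def validate(self, pair: GenomePair | None = None) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError(
                "contamination_fraction must be in [0, 1], got "
                f"{self.contamination_fraction}"
            )
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if len(self.quality_model) < 1:
            raise ValueError("quality_model must have at least one value")
        if pair is not None and self.read_length > pair.length:
            raise ValueError(
                f"read_length {self.read_length} exceeds genome length "
                f"{pair.length}"
            )


@dataclass
class LabeledReadSet:
    """Simulated reads plus per-read ground truth.

    ``truth`` maps read id to its origin genome label ('A' or 'B');
    ``origin_coords`` stores (genome, start, end, strand) on the forward
    strand, 0-based half-open.
    """

    reads: list[Read]
    truth: dict[str, str]
    origin_coords: dict[str, tuple[str, int, int, str]]
    config: MixtureConfig | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def write(self, fastq_path: str | Path, truth_path: str | Path | None = None) -> None:
        write_fastq(self.reads, fastq_path)
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                if self.config is not None:
                    fh.write(f"# seed={self.config.seed}\n")
                fh.write("read_id\torigin\tchrom\tstart\tend\tstrand\n")
                for r in self.reads:
                    genome, start, end, strand = self.origin_coords[r.id]
                    fh.write(
                        f"{r.id}\t{self.truth[r.id]}\t{genome}\t{start}\t{end}\t{strand}\n"
                    )


# Quality jitter is +/-2 integer steps around the linear decay line, with a
# floor of Q2 (and a ceiling of Q41, the common sequencer maximum).
_JITTER = 2
_Q_FLOOR = 2
_Q_CEIL = 41


def simulate_reads(pair: GenomePair, cfg: MixtureConfig) -> LabeledReadSet:
    """Simulate a single-end read mixture from a genome pair.

    Per read: origin genome ~ Bernoulli(contamination_fraction), start
    uniform, strand uniform (minus-strand reads emitted as reverse
    complements), substitution errors at ``error_rate``, qualities decaying
    linearly from ``quality_model[0]`` to ``quality_model[-1]`` with bounded
    integer jitter. No indels, no adapters.
    """
    cfg.validate(pair)
    n, rl = cfg.n_reads, cfg.read_length
    seqs = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_origin, rng_pos, rng_strand, rng_err, rng_qual = (
        np.random.default_rng(s) for s in seqs
    )

    genomes = {
        "A": np.frombuffer(pair.seq_a.encode(), dtype=np.uint8),
        "B": np.frombuffer(pair.seq_b.encode(), dtype=np.uint8),
    }
    code_of = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i

    origin_b = rng_origin.random(n) < cfg.contamination_fraction
    starts = rng_pos.integers(0, pair.length - rl + 1, size=n)
    minus = rng_strand.random(n) < 0.5

    # Gather read windows per origin genome.
    offsets = np.arange(rl)
    windows = np.empty((n, rl), dtype=np.uint8)
    for label, is_b in (("A", False), ("B", True)):
        idx = np.nonzero(origin_b == is_b)[0]
        if idx.size:
            windows[idx] = genomes[label][starts[idx, None] + offsets]

    codes = code_of[windows]
    # Minus strand: reverse complement the sampled window.
    if minus.any():
        m = np.nonzero(minus)[0]
        codes[m] = (3 - codes[m])[:, ::-1]

    if cfg.error_rate > 0:
        err = rng_err.random((n, rl)) < cfg.error_rate
        shift = rng_err.integers(1, 4, size=(n, rl))
        codes = np.where(err, (codes + shift) % 4, codes)

    qm = np.asarray(cfg.quality_model, dtype=float)
    line = np.linspace(qm[0], qm[-1], rl)
    quals = np.rint(line) + rng_qual.integers(-_JITTER, _JITTER + 1, size=(n, rl))
    quals = np.clip(quals, _Q_FLOOR, _Q_CEIL).astype(np.uint8) + 33

    base_bytes = _BASES[codes]
    width = len(str(max(n - 1, 0)))
    reads: list[Read] = []
    truth: dict[str, str] = {}
    coords: dict[str, tuple[str, int, int, str]] = {}
    for i in range(n):
        rid = f"r{i:0{width}d}"
        reads.append(
            Read(rid, base_bytes[i].tobytes().decode(), quals[i].tobytes().decode())
        )
        label = "B" if origin_b[i] else "A"
        truth[rid] = label
        coords[rid] = (label, int(starts[i]), int(starts[i]) + rl,
                       "-" if minus[i] else "+")
    return LabeledReadSet(reads=reads, truth=truth, origin_coords=coords, config=cfg)


def simulate_count_table(
    n_samples_per_group: int,
    group_profiles: Mapping[str, Mapping[str, float]],
    library_sizes: int | Sequence[int],
    dispersion: float = 0.0,
    seed: int = 0,
    profile_tol: float = 1e-6,
):
    """Draw grouped biotype count tables around per-group proportion vectors.

    Counts are multinomial per sample (Dirichlet-multinomial when
    ``dispersion`` > 0, with Dirichlet concentration profile/dispersion).
    Returns a :class:`~seracon.composition.BiotypeCountTable`.
    """
    from .composition import BiotypeCountTable

    if len(group_profiles) < 2:
        raise ValueError("at least two groups are required")
    if n_samples_per_group < 1:
        raise ValueError("n_samples_per_group must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")

    features: list[str] | None = None
    for name, prof in group_profiles.items():
        if features is None:
            features = list(prof)
        elif list(prof) != features:
            raise ValueError("all group profiles must share the same features")
        total = sum(prof.values())
        if abs(total - 1.0) > profile_tol:
            raise ValueError(
                f"profile for group {name!r} sums to {total}, expected 1"
            )
    assert features is not None

    n_total = n_samples_per_group * len(group_profiles)
    if np.isscalar(library_sizes):
        sizes = [int(library_sizes)] * n_total
    else:
        sizes = [int(s) for s in library_sizes]  # type: ignore[union-attr]
        if len(sizes) != n_total:
            raise ValueError(
                f"library_sizes has {len(sizes)} entries, expected {n_total}"
            )
    if any(s <= 0 for s in sizes):
        raise ValueError("library sizes must be positive")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, sample_ids, groups = [], [], []
    k = 0
    for name, prof in group_profiles.items():
        p = np.array([prof[f] for f in features], dtype=float)
        p = p / p.sum()
        for j in range(n_samples_per_group):
            if dispersion > 0:
                p_s = rng.dirichlet(p / dispersion)
            else:
                p_s = p
            rows.append(rng.multinomial(sizes[k], p_s))
            sample_ids.append(f"{name}_{j + 1}")
            groups.append(name)
            k += 1

    counts = pd.DataFrame(rows, index=sample_ids, columns=features)
    biotypes = pd.Series(features, index=features, name="biotype")
    sample_groups = pd.Series(groups, index=sample_ids, name="group")
    return BiotypeCountTable(counts=counts, biotypes=biotypes,
                             sample_groups=sample_groups)


def simulate_cq_table(
    n_samples: int,
    gene_means: Mapping[str, float],
    stable_controls: Sequence[str],
    noise_sd: float,
    seed: int = 0,
    sample_offset_sd: float = 0.5,
    volatile_sd: float = 1.5,
) -> pd.DataFrame:
    """Simulate a samples x genes Cq table with group-free structure.

    Cq = gene mean + per-sample offset (shared across genes, emulating
    variable RNA input) + N(0, noise_sd). Genes not listed in
    ``stable_controls`` additionally receive a per-sample biological term
    N(0, volatile_sd), so controls are strictly more stable.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    controls = list(stable_controls)
    if len(controls) < 2:
        raise ValueError("at least 2 stable controls are required (geNorm "
                         "stability is undefined otherwise)")
    missing = [g for g in controls if g not in gene_means]
    if missing:
        raise ValueError(f"stable controls absent from gene_means: {missing}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = list(gene_means)
    offsets = rng.normal(0.0, sample_offset_sd, size=n_samples)
    data = np.empty((n_samples, len(genes)))
    for j, g in enumerate(genes):
        col = gene_means[g] + offsets
        if g not in controls:
            col = col + rng.normal(0.0, volatile_sd, size=n_samples)
        col = col + rng.normal(0.0, noise_sd, size=n_samples)
        data[:, j] = col
    index = [f"s{i + 1}" for i in range(n_samples)]
    return pd.DataFrame(data, index=index, columns=genes)
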