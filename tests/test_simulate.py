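import math

import numpy as np
import pandas as pd
import pytest

from seracon.classify import classify_reads
from seracon.composition import pearson_cluster, rpm_normalize
from seracon.qpcr import genorm_m_values
from seracon.simulate import (
    GenomePair,
    MixtureConfig,
    evolve_genome_pair,
    revcomp,
    simulate_cq_table,
    simulate_count_table,
    simulate_reads,
)


class TestEvolveGenomePair:
    def test_zero_divergence_identity(self):
        pair = evolve_genome_pair(5000, 0.0, seed=1)
        assert pair.seq_a == pair.seq_b

    def test_divergence_calibration(self):
        # realized mismatch rate within 3 binomial SD of the parameter
        pair = evolve_genome_pair(20000, 0.15, seed=7)
        sd = math.sqrt(0.15 * 0.85 / 20000)
        assert abs(pair.observed_divergence() - 0.15) <= 3 * sd

    def test_out_of_range_divergence(self):
        with pytest.raises(ValueError, match="divergence"):
            evolve_genome_pair(5000, 1.2, seed=1)

    def test_too_short(self):
        with pytest.raises(ValueError, match="length"):
            evolve_genome_pair(999, 0.1, seed=1)

    def test_equal_lengths_and_alphabet(self):
        pair = evolve_genome_pair(3000, 0.5, seed=3)
        assert len(pair.seq_a) == len(pair.seq_b) == 3000
        assert set(pair.seq_a) <= set("ACGT")
        assert set(pair.seq_b) <= set("ACGT")

    def test_deterministic(self):
        assert evolve_genome_pair(2000, 0.2, seed=5) == evolve_genome_pair(
            2000, 0.2, seed=5
        )


class TestSimulateReads:
    def test_zero_contamination_all_a(self, pair_015):
        cfg = MixtureConfig(n_reads=500, contamination_fraction=0.0, seed=1)
        rs = simulate_reads(pair_015, cfg)
        assert set(rs.truth.values()) == {"A"}

    def test_label_frequency_binomial(self, pair_015):
        # fraction of B labels converges to c (3 SD at n=1e5)
        c = 0.3
        cfg = MixtureConfig(n_reads=100_000, contamination_fraction=c, seed=2)
        rs = simulate_reads(pair_015, cfg)
        n_b = sum(1 for v in rs.truth.values() if v == "B")
        sd = math.sqrt(c * (1 - c) * cfg.n_reads)
        assert abs(n_b - c * cfg.n_reads) <= 3 * sd

    def test_identical_genomes_all_both(self):
        pair = evolve_genome_pair(5000, 0.0, seed=9)
        cfg = MixtureConfig(n_reads=200, contamination_fraction=0.5, seed=3)
        rs = simulate_reads(pair, cfg)
        result = classify_reads(rs.reads, pair.seq_a, pair.seq_b)
        assert result.n_both == 200

    def test_deterministic_fastq_bytes(self, pair_015, tmp_path):
        cfg = MixtureConfig(n_reads=300, contamination_fraction=0.2, seed=4)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_reads(pair_015, cfg).write(p1)
        simulate_reads(pair_015, cfg).write(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_read_too_long(self, pair_015):
        cfg = MixtureConfig(n_reads=10, contamination_fraction=0.0,
                            read_length=pair_015.length + 1)
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(pair_015, cfg)

    def test_origin_coords_recover_read(self, pair_015):
        cfg = MixtureConfig(n_reads=200, contamination_fraction=0.5, seed=5)
        rs = simulate_reads(pair_015, cfg)
        genomes = {"A": pair_015.seq_a, "B": pair_015.seq_b}
        for r in rs.reads:
            genome, start, end, strand = rs.origin_coords[r.id]
            window = genomes[genome][start:end]
            assert r.seq == (window if strand == "+" else revcomp(window))

    def test_error_rate_realized(self, pair_015):
        cfg = MixtureConfig(n_reads=2000, contamination_fraction=0.0,
                            error_rate=0.1, seed=6)
        rs = simulate_reads(pair_015, cfg)
        mismatches = 0
        total = 0
        for r in rs.reads:
            genome, start, end, strand = rs.origin_coords[r.id]
            window = pair_015.seq_a[start:end]
            truth = window if strand == "+" else revcomp(window)
            mismatches += sum(a != b for a, b in zip(r.seq, truth))
            total += len(r.seq)
        rate = mismatches / total
        sd = math.sqrt(0.1 * 0.9 / total)
        assert abs(rate - 0.1) <= 4 * sd

    def test_quality_model_decay(self, pair_015):
        cfg = MixtureConfig(n_reads=500, contamination_fraction=0.0,
                            quality_model=(38.0, 10.0), seed=8)
        rs = simulate_reads(pair_015, cfg)
        q = np.array([[ord(c) - 33 for c in r.qual] for r in rs.reads])
        means = q.mean(axis=0)
        assert means[0] > means[-1] + 20
        assert q.min() >= 2

    def test_invalid_contamination(self):
        with pytest.raises(ValueError, match="contamination"):
            MixtureConfig(n_reads=10, contamination_fraction=1.5).validate()


class TestSimulateCountTable:
    PROFILES = {
        "pellet": {"miRNA": 0.7, "mRNA": 0.1, "rRNA": 0.2},
        "supernatant": {"miRNA": 0.1, "mRNA": 0.7, "rRNA": 0.2},
    }

    def test_shapes_and_groups(self):
        table = simulate_count_table(3, self.PROFILES, 10000, seed=1)
        assert table.counts.shape == (6, 3)
        assert list(table.sample_groups.unique()) == ["pellet", "supernatant"]
        assert (table.counts.sum(axis=1) == 10000).all()

    def test_profile_recovered(self):
        table = simulate_count_table(3, self.PROFILES, 100_000, seed=2)
        pellet = table.counts.loc[table.sample_groups == "pellet"]
        props = (pellet / 100_000).mean(axis=0)
        assert abs(props["miRNA"] - 0.7) < 0.02

    def test_separated_profiles_cluster_by_group(self):
        table = simulate_count_table(3, self.PROFILES, 50_000, seed=3)
        tree = pearson_cluster(rpm_normalize(table))
        cut = tree.cut(2)
        groups = table.sample_groups
        labels = {g: {cut[s] for s in groups.index[groups == g]} for g in
                  ("pellet", "supernatant")}
        assert labels["pellet"].isdisjoint(labels["supernatant"])
        assert len(labels["pellet"]) == len(labels["supernatant"]) == 1

    def test_bad_profile_sum(self):
        bad = {"g1": {"x": 0.5, "y": 0.4}, "g2": {"x": 0.5, "y": 0.5}}
        with pytest.raises(ValueError, match="sums to"):
            simulate_count_table(2, bad, 1000)

    def test_zero_library_size(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_count_table(3, self.PROFILES, [0, 1, 1, 1, 1, 1])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            simulate_count_table(2, {"only": {"x": 1.0}}, 1000)

    def test_dispersion_adds_variance(self):
        tight = simulate_count_table(10, self.PROFILES, 10_000, dispersion=0.0, seed=4)
        loose = simulate_count_table(10, self.PROFILES, 10_000, dispersion=0.05, seed=4)
        v_tight = tight.counts["miRNA"].iloc[:10].var()
        v_loose = loose.counts["miRNA"].iloc[:10].var()
        assert v_loose > v_tight


class TestSimulateCqTable:
    MEANS = {"U6": 18.0, "U2": 20.0, "miR-103a-3p": 22.0, "miR-24-3p": 23.0,
             "target1": 25.0, "target2": 28.0}
    CONTROLS = ["U6", "U2", "miR-103a-3p", "miR-24-3p"]

    def test_noiseless_controls_have_zero_m(self):
        cq = simulate_cq_table(6, self.MEANS, self.CONTROLS, noise_sd=0.0, seed=1)
        m = genorm_m_values(cq, self.CONTROLS)
        assert np.allclose(m.values, 0.0, atol=1e-12)

    def test_controls_more_stable_than_volatile(self):
        cq = simulate_cq_table(8, self.MEANS, self.CONTROLS, noise_sd=0.2, seed=2)
        m = genorm_m_values(cq)
        assert max(m[g] for g in self.CONTROLS) < min(
            m["target1"], m["target2"]
        )

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="n_samples"):
            simulate_cq_table(1, self.MEANS, self.CONTROLS, noise_sd=0.1)

    def test_too_few_controls(self):
        with pytest.raises(ValueError, match="controls"):
            simulate_cq_table(4, self.MEANS, ["U6"], noise_sd=0.1)

    def test_deterministic(self):
        a = simulate_cq_table(4, self.MEANS, self.CONTROLS, noise_sd=0.3, seed=9)
        b = simulate_cq_table(4, self.MEANS, self.CONTROLS, noise_sd=0.3, seed=9)
        pd.testing.assert_frame_equal(a, b)
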