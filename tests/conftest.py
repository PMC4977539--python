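import numpy as np
import pytest

from seracon.io import Read
from seracon.simulate import MixtureConfig, evolve_genome_pair, simulate_reads


@pytest.fixture(scope="session")
def pair_015():
    """A 20 kb genome pair at 15% divergence."""
    return evolve_genome_pair(20000, 0.15, seed=42)


@pytest.fixture(scope="session")
def mixture_015(pair_015):
    """2,000 error-free reads at contamination fraction 0.3."""
    cfg = MixtureConfig(n_reads=2000, contamination_fraction=0.3, seed=7)
    return simulate_reads(pair_015, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_read(seq, q=40, rid="r1"):
    return Read(rid, seq, chr(q + 33) * len(seq))
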