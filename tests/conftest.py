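import numpy as np
import pytest

from hdnascan.motif_scan import motifs_to_track, scan_hdna
from hdnascan.synthetic_data import SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def tiny_genome():
    """A 1 Mb synthetic genome with two rDNA-like arrays (shared across tests)."""
    spec = SyntheticSpec(seed=7, genome_len=1_000_000, n_arrays=2, gene_count=10)
    return generate_genome(spec)


@pytest.fixture(scope="session")
def tiny_hdna(tiny_genome):
    return scan_hdna(tiny_genome.record)


@pytest.fixture(scope="session")
def tiny_hdna_track(tiny_hdna):
    return motifs_to_track(tiny_hdna)


@pytest.fixture
def random_seq():
    """Factory for random ACGT sequences with a chosen GC content."""

    def make(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list("ACGT"), size=n, p=p))

    return make
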