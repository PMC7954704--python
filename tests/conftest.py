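import numpy as np
import pytest

from strandweave import simdata as sd


@pytest.fixture(scope="session")
def small_genome():
    """3 x 2 Mbp diploid genome, ~6k het SNVs."""
    return sd.simulate_genome(sd.GenomeSpec((2_000_000,) * 3, 1.0e-3, seed=1))


@pytest.fixture(scope="session")
def small_contigs(small_genome):
    return sd.fragment_contigs(small_genome, target_n50=400_000, seed=1)


@pytest.fixture(scope="session")
def small_strandseq(small_genome, small_contigs):
    return sd.simulate_strandseq(
        small_genome, small_contigs, n_cells=60, reads_per_cell=3000,
        sce_rate=0.2, background=0.05, seed=1)


@pytest.fixture(scope="session")
def clean_strandseq(small_genome, small_contigs):
    """No background, no SCEs: every cell is a pure strand state."""
    return sd.simulate_strandseq(
        small_genome, small_contigs, n_cells=40, reads_per_cell=3000,
        sce_rate=0.0, background=0.0, seed=2)
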