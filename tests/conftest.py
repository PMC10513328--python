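import numpy as np
import pytest

from snpanchor import (
    GenotypeMatrix,
    implant_probes,
    make_genome,
    simulate_panel,
)


@pytest.fixture(scope="session")
def small_genome():
    return make_genome(seed=11, length=10_000, n_chrom=2)


@pytest.fixture(scope="session")
def implanted(small_genome):
    """(genome-with-probes, probes, truth) — 40 clean implants, mixed strand."""
    return implant_probes(small_genome, seed=12, n_probes=40, probe_len=70)


@pytest.fixture(scope="session")
def panel_with_dups():
    """26 accessions, 350 loci, 2 duplicate and 2 divergent implanted pairs."""
    return simulate_panel(
        seed=13,
        n_accessions=26,
        loci=350,
        n_duplicate_pairs=2,
        dup_noise=0.0005,
        n_divergent_pairs=2,
        divergent_noise=0.05,
    )


@pytest.fixture()
def tiny_matrix():
    return GenotypeMatrix(
        ["a", "b", "c"],
        ["L1", "L2", "L3", "L4"],
        np.array(
            [
                ["A", "A", "N", "A"],
                ["A", "A", "T", "A"],
                ["A", "G", "T", "R"],
            ],
            dtype="<U1",
        ),
    )
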