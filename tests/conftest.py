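import numpy as np
import pytest

from polyhub import synthetic_data as syn


@pytest.fixture(scope="session")
def genome_small():
    """Two 5 Mb chromosomes at 10 kb resolution."""
    return syn.default_genome(2, 5_000_000, 10_000)


@pytest.fixture(scope="session")
def truth_basic(genome_small):
    """Full-featured truth (domains, TADs, loops, hubs) on the small genome."""
    return syn.default_truth(
        genome_small,
        n_domains=20,
        n_tads=6,
        tad_length=(400_000, 800_000),
        n_loops=15,
        n_hub_pairs=15,
        seed=1,
    )


@pytest.fixture(scope="session")
def genome_hic():
    """Two 10 Mb chromosomes used for aggregate-recovery simulations."""
    return syn.default_genome(2, 10_000_000, 10_000)


@pytest.fixture(scope="session")
def hub_truth(genome_hic):
    """Sparse hub-only truth: single-bin domains, every in-range pair a hub.

    Sparse implants keep ICE balancing and the distance-decay expectation
    essentially unbiased, so aggregate centers recover the implanted factor.
    """
    return syn.default_truth(
        genome_hic,
        n_domains=10,
        domain_length=(8_000, 12_000),
        n_tads=0,
        n_loops=0,
        n_hub_pairs=None,
        hub_sep=(1_000_000, 6_000_000),
        seed=1,
    )


@pytest.fixture(scope="session")
def calibration_truth(genome_small):
    """Identical occupancy in both conditions (isolates the IP confound)."""
    return syn.default_truth(
        genome_small,
        n_domains=20,
        n_tads=6,
        tad_length=(400_000, 800_000),
        n_loops=15,
        n_hub_pairs=15,
        hub_factors={"A": 3.0, "B": 3.0},
        occupancy={"A": 8.0, "B": 8.0},
        seed=1,
    )


@pytest.fixture(scope="session")
def occupancy_truth(genome_small):
    """Occupancy halved in condition B (known effect to recover)."""
    return syn.default_truth(
        genome_small,
        n_domains=20,
        n_tads=6,
        tad_length=(400_000, 800_000),
        n_loops=15,
        n_hub_pairs=15,
        hub_factors={"A": 3.0, "B": 3.0},
        occupancy={"A": 8.0, "B": 4.0},
        seed=1,
    )


@pytest.fixture(scope="session")
def null_expression_truth(genome_small):
    """No gene-level effects: used for null DE simulations."""
    truth = syn.default_truth(
        genome_small, n_domains=5, n_tads=0, n_loops=0, n_hub_pairs=0,
        n_genes=2000, seed=1,
    )
    return truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
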