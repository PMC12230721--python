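import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))  # for the oracle helpers

from panforge.orthogroups import Orthogroup, OrthogroupTable, infer_orthogroups
from panforge.simulate import simulate_pangenome, to_protein_sets


@pytest.fixture
def toy_table() -> OrthogroupTable:
    """3 genomes: one core OG, one 2-genome OG, one orphan paralog pair, one
    orphan single gene."""
    rows = [
        Orthogroup(0, {"gA": ["a1"], "gB": ["b1"], "gC": ["c1"]}),
        Orthogroup(1, {"gA": ["a2"], "gB": ["b2"]}),
        Orthogroup(2, {"gC": ["c2", "c3"]}),
        Orthogroup(3, {"gB": ["b3"]}),
    ]
    return OrthogroupTable(["gA", "gB", "gC"], rows)


@pytest.fixture(scope="session")
def small_sim():
    """5 genomes, zero noise: families must be recovered exactly."""
    genomes, truth = simulate_pangenome(
        n_genomes=5,
        n_core_families=12,
        n_accessory_families=4,
        mutation_rate=0.0,
        duplication_prob=0.0,
        n_orphans_per_genome=1,
        seed=42,
    )
    return genomes, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """The reference study conditions: 10 genomes, 50 core + 20 accessory
    families, 5% duplication, 5% per-site mutation."""
    genomes, truth = simulate_pangenome(
        n_genomes=10,
        n_core_families=50,
        n_accessory_families=20,
        duplication_prob=0.05,
        mutation_rate=0.05,
        seed=1,
    )
    return genomes, truth


@pytest.fixture(scope="session")
def noisy_table(noisy_sim):
    genomes, _ = noisy_sim
    return infer_orthogroups(to_protein_sets(genomes))
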