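import numpy as np
import pytest

from trdscan import (
    GenotypeMatrix,
    MarkerInfo,
    Pedigree,
    PedigreeRecord,
    SimulationConfig,
    simulate_ail,
)


@pytest.fixture
def trio_matrix():
    """Hand-built sire/dam/child matrix over four informative markers."""
    markers = [MarkerInfo(f"m{j}", "1", 1000 * (j + 1)) for j in range(4)]
    # codes: 0=HOM_A 1=HET 2=HOM_B -1=missing
    calls = np.array(
        [
            [0, 1, 2, 1],  # sire
            [2, 0, 1, 1],  # dam
            [1, 1, 2, 0],  # child (all Mendelian-consistent)
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["sire", "dam", "child"], markers, calls)


@pytest.fixture
def trio_pedigree():
    return Pedigree(
        [
            PedigreeRecord("sire", None, None, 0, "M"),
            PedigreeRecord("dam", None, None, 0, "F"),
            PedigreeRecord("child", "sire", "dam", 1, "M"),
        ]
    )


@pytest.fixture(scope="session")
def null_ail():
    """A small neutral AIL shared by tests that only need realistic structure."""
    cfg = SimulationConfig(
        n_chromosomes=2,
        markers_per_chromosome=50,
        chromosome_length_cM=80.0,
        generations=5,
        families_per_generation=40,
        litter_size=4,
        seed=42,
    )
    genotypes, pedigree, truth = simulate_ail(cfg)
    return cfg, genotypes, pedigree
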