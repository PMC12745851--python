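import numpy as np
import pytest

from invadibe.genotype_io import GenotypeMatrix
from invadibe.pairtable import build_pair_table
from invadibe.popgen import pairwise_individual_fst
from invadibe.simulate import SimParams, simulate_dataset


@pytest.fixture
def toy_matrix():
    """6 samples x 5 loci with a deliberate mix of patterns: a monomorphic
    locus, a fixed difference between the first/last three samples, a fully
    heterozygous locus and some missingness."""
    dosages = np.array([
        [0, 0, 1, 2, 0],
        [0, 0, 1, 1, 0],
        [0, 0, 1, 0, 1],
        [0, 2, 1, 2, 0],
        [0, 2, 1, 1, 2],
        [0, 2, 1, 0, 1],
    ])
    missing = np.zeros_like(dosages, dtype=bool)
    missing[0, 4] = True
    return GenotypeMatrix([f"s{i}" for i in range(6)],
                          [f"L{j}" for j in range(5)], dosages, missing)


@pytest.fixture(scope="session")
def study_sim():
    """One study-like synthetic dataset reused across tests (fixed seed)."""
    return simulate_dataset(SimParams(seed=11))


@pytest.fixture(scope="session")
def study_pairs(study_sim):
    mat = pairwise_individual_fst(study_sim.genotypes)
    return build_pair_table(study_sim.metadata, mat)
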