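import logging

import numpy as np
import pytest

from kbpbm import (
    assemble_probes,
    default_dimer_suite,
    expand_iupac,
    hamming_matrix,
    make_fixtures,
    pcoa,
    select_representatives,
)
from kbpbm.probe_design import DEFAULT_FLANKS

logging.getLogger("kbpbm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def suite():
    return default_dimer_suite()


@pytest.fixture(scope="session")
def mini_bundle():
    """Miniature end-to-end dataset: 32 cores x 2 flanks x 3 replicates."""
    return make_fixtures(seed=1)


@pytest.fixture(scope="session")
def desk_design():
    """Desk-scale array: 200 representative 11-mer cores x 4 flanks x 3 reps.

    Cores are chosen by the full PCoA + k-medoids path from a seeded
    1,024-point subsample of the 6,912-member kappaB k-mer space.
    """
    space = expand_iupac("RGGRNNHHYYB")
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(1).spawn(1)[0])
    )
    idx = np.sort(rng.choice(len(space.kmers), 1024, replace=False))
    kmers = [space.kmers[i] for i in idx]
    embedding = pcoa(hamming_matrix(kmers), retained_fraction=0.9)
    chosen = select_representatives(embedding, k=200, seed=1)
    return assemble_probes(
        [kmers[i] for i in chosen], DEFAULT_FLANKS, replicates=3, capacity=15_000
    )
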