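import numpy as np
import pytest

from depthcline.io import GenotypeTable
from depthcline import simdata


@pytest.fixture()
def toy_genotypes() -> GenotypeTable:
    """Eight diploid fish, two loci, one missing call."""
    calls = np.array(
        [
            [[1, 1], [3, 4]],
            [[1, 2], [3, 3]],
            [[2, 2], [4, 4]],
            [[1, 2], [0, 0]],
            [[2, 2], [3, 4]],
            [[1, 1], [4, 4]],
            [[1, 2], [3, 3]],
            [[2, 2], [3, 4]],
        ]
    )
    return GenotypeTable([f"f{i}" for i in range(8)], ["LocA", "LocB"], calls)


@pytest.fixture()
def two_pop_cohort():
    """Two diverged species of 40 fish each with distinct phenotypes."""
    pool = simdata.simulate_allele_frequencies(2, target_fst=0.10, seed=7)
    specs = [
        simdata.SpeciesPhenotypeSpec(200.0, 15.0, 37.8, 2.63, 32.0, 12.0),
        simdata.SpeciesPhenotypeSpec(350.0, 15.0, 27.7, 2.83, 8.0, 12.0),
    ]
    return simdata.simulate_individuals(pool, specs, [40, 40], seed=7)
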