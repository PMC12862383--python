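import numpy as np
import pytest

import shortsplice as ss


@pytest.fixture(scope="session")
def small_cohort() -> ss.Cohort:
    """Shared 60-gene cohort with default study conditions."""
    return ss.generate_cohort(ss.CohortConfig(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def default_tree() -> ss.SpeciesTree:
    return ss.SpeciesTree("((Pbur,(Ptet,Pcau)),Tthe);", "Pbur")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
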