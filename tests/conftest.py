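import numpy as np
import pytest

import rostrumorph as rm


@pytest.fixture(scope="session")
def small_assemblage():
    """One deterministic synthetic assemblage, 10 specimens per subzone."""
    return rm.generate_assemblage(rm.default_truth(seed=11), 10)


@pytest.fixture(scope="session")
def medium_assemblage():
    """Larger assemblage used by ordination/allometry tests."""
    return rm.generate_assemblage(rm.default_truth(seed=5), 30)


@pytest.fixture(scope="session")
def aligned_medium(medium_assemblage):
    return rm.gpa_align(medium_assemblage.landmarks, slide=True)


@pytest.fixture(scope="session")
def morphospace(aligned_medium):
    return rm.pca_fit(aligned_medium)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_configuration(rng, specimen_id="rand"):
    """A non-degenerate random 22-landmark configuration."""
    return rm.LandmarkConfiguration(specimen_id, rng.normal(0, 10, (22, 3)))
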