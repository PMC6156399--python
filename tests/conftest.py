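import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snmda import EntityIndex, SimilarityMatrix, figure2_fixture

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def fig2():
    return figure2_fixture()


@pytest.fixture
def identity_sims(fig2):
    """Identity similarity priors over the toy network's entities."""
    mfs = SimilarityMatrix(np.eye(fig2.n_mirnas), fig2.mirna_index)
    dss = SimilarityMatrix(np.eye(fig2.n_diseases), fig2.disease_index)
    return mfs, dss


@pytest.fixture
def tiny_index():
    return EntityIndex(["a", "b", "c"])
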