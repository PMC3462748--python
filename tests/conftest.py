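import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20121002)


@pytest.fixture(scope="session")
def catalog_annotations():
    """Annotated synthetic catalog precursors (computed once per session)."""
    from barnapep.annotate import annotate_protein
    from barnapep.catalog import catalog_precursors

    return {
        name: annotate_protein(protein, name)
        for name, (protein, _) in catalog_precursors().items()
    }
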