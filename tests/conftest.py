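import numpy as np
import pytest

import connkit as ck


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Matrix-route cohort with a planted disruption and behaviour network."""
    spec = ck.CohortSpec(
        n_patients=12,
        n_controls=18,
        n_regions=30,
        disrupted_edges=ck.planted_component(30, 15),
        behavior_edges=ck.planted_component(30, 12, offset=12),
        seed=42,
    )
    return ck.generate_cohort(spec)


@pytest.fixture(scope="session")
def atlas():
    return ck.load_atlas()
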