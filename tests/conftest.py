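import numpy as np
import pytest

import chcevol as c


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared by read-only tests."""
    return c.run_synthetic_study(c.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def lct(study):
    return c.log_contrast(study.composition)


@pytest.fixture(scope="session")
def nested_design(lct):
    return c.NestedDesign(
        outer=lct.meta["species"].to_numpy(),
        inner=lct.meta["population"].to_numpy(),
        specimens=lct.specimen_ids,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
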