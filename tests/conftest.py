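import numpy as np
import pytest

import crownlma as cl


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic study-scale dataset (n = 585), shared read-only."""
    return cl.generate_dataset(cl.GeneratorConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240428)
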