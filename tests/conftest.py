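import numpy as np
import pytest

import voleconn as v


@pytest.fixture(scope="session")
def null_cohort():
    """Default-design cohort with no planted effects (90 retained cells)."""
    config = v.SyntheticConfig(seed=1234)
    return v.generate_cohort(config)


@pytest.fixture(scope="session")
def null_stack(null_cohort):
    panel, _, _ = null_cohort
    return v.build_connectome_stack(panel)


@pytest.fixture(scope="session")
def null_edge_table(null_stack):
    return null_stack.edge_long_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(97)
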