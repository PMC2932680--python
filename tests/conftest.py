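import numpy as np
import pytest

import leadsim as ls
from leadsim.simulator import SimConfig, run


@pytest.fixture(scope="session")
def dyad_group():
    return ls.build_dyad_group(3, 10)


@pytest.fixture(scope="session")
def het10_group():
    return ls.build_macaque_group(10, True, rng_seed=42)


@pytest.fixture(scope="session")
def hom10_group():
    return ls.build_macaque_group(10, False, rng_seed=7)


@pytest.fixture(scope="session")
def short_het10_result(het10_group):
    """A 3-day heterogeneous run with the event log, reused across tests."""
    cfg = SimConfig(group=het10_group, max_days=3, replicates=1, rng_seed=11,
                    record_events=True)
    return cfg, run(cfg, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
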