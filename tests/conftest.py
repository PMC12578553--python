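import numpy as np
import pytest

import distress_patterns as dp


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across test modules."""
    return dp.generate_cohort(dp.GeneratorConfig(n=1500, seed=7))


@pytest.fixture(scope="session")
def small_discovery(small_cohort):
    """Discovery run on the small cohort with size-scaled density params."""
    cfg = dp.DiscoveryConfig(auto_scale=True)
    return dp.run_discovery(small_cohort.items, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
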