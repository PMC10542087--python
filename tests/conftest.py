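import numpy as np
import pytest

import dfcstates as d


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort shared across tests: 6+6 subjects, 24 regions."""
    cfg = d.CohortConfig(seed=42, n_group_a=6, n_group_b=6, n_regions=24)
    series, meta, truth = d.generate_cohort(cfg)
    return cfg, series, meta, truth


@pytest.fixture(scope="session")
def small_wfcs(small_cohort):
    cfg, series, meta, truth = small_cohort
    spec = d.WindowSpec(30, 3)
    return [d.windowed_fc(d.preprocess(s, cfg.n_discard), spec) for s in series]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
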