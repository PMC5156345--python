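import numpy as np
import pytest

import sealdive as sd


@pytest.fixture(scope="session")
def deployment12():
    """Default-condition deployment: 12 dives incl. one drift dive, seed 42."""
    cfg = sd.SimConfig(seed=42, n_dives=12)
    dep, truth = sd.simulate_deployment(cfg)
    return cfg, dep, truth


@pytest.fixture(scope="session")
def analysis12(deployment12):
    _, dep, _ = deployment12
    return sd.analyze_deployment(dep)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
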