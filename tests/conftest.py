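import numpy as np
import pytest

from antdol.threshold_model import SimConfig, TypeParams, run_batch


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def pure_x_small():
    """A small, fast pure colony in the stable demand regime."""
    tp = TypeParams("X", mu=10.0, sigma=0.1, alpha=2.0)
    cfg = SimConfig(composition=((tp, 16),), delta=0.6, T=2000, seed=11)
    return run_batch(cfg, 10)


@pytest.fixture(scope="session")
def mixed_small():
    """A small mixed colony (threshold-mean difference only)."""
    x = TypeParams("X", mu=10.0, sigma=0.1, alpha=2.0)
    y = TypeParams("Y", mu=20.0, sigma=0.1, alpha=2.0)
    cfg = SimConfig(composition=((x, 8), (y, 8)), delta=0.6, T=2000, seed=12)
    return run_batch(cfg, 10)
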