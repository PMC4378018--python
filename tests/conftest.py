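import numpy as np
import pytest

from cpgbm.synthetic_data import SyntheticConfig


@pytest.fixture(scope="session")
def bimodal_sample() -> np.ndarray:
    """10,000 draws from 0.45*N(0.36, 0.08^2) + 0.55*N(0.74, 0.15^2)."""
    rng = np.random.default_rng(42)
    comp = rng.random(10_000) < 0.45
    return np.where(comp,
                    rng.normal(0.36, 0.08, 10_000),
                    rng.normal(0.74, 0.15, 10_000))


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Default study conditions at a reduced gene count for unit tests."""
    return SyntheticConfig(n_genes=1000, seed=7)
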