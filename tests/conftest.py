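import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qbe import GeneratorConfig, TheoryDataset, demo_datasets, generate_theory

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo():
    """The four bundled demonstration theories, keyed by name."""
    return {ds.name: ds for ds in demo_datasets()}


@pytest.fixture()
def random_dataset():
    """Factory for small random (seeded) theory datasets."""

    def make(seed: int = 0, n_min: int = 5, n_max: int = 15) -> TheoryDataset:
        cfg = GeneratorConfig(n_min=n_min, n_max=n_max, seed=seed)
        return generate_theory(f"rand_{seed}", cfg, np.random.default_rng(seed))

    return make
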