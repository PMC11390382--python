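import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_bags():
    """100 clustered hard-negative bags on a 16x16 grid, session-cached."""
    from natmil.synthetic import SyntheticBagSpec, generate_feature_bags

    spec = SyntheticBagSpec(n_bags=100, grid_height=16, grid_width=16, d=16,
                            tumor_fraction=0.08, cluster=True,
                            class_separation=5.0, seed=11)
    return generate_feature_bags(spec)


@pytest.fixture(scope="session")
def easy_bags():
    """Scattered, linearly separable bags (no hard negatives)."""
    from natmil.synthetic import SyntheticBagSpec, generate_feature_bags

    spec = SyntheticBagSpec(n_bags=40, grid_height=8, grid_width=8, d=16,
                            tumor_fraction=0.15, cluster=False,
                            class_separation=3.0, seed=5)
    return generate_feature_bags(spec)
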