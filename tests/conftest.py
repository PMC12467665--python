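import numpy as np
import pytest

from flfsi import rgb2dpca, synthetic


@pytest.fixture(scope="session")
def toy_stack() -> np.ndarray:
    """Seeded width-4 stack used for exhaustive swarm checks (d=4, 4096 masks)."""
    rng = np.random.default_rng(42)
    return rgb2dpca.as_stack(rng.uniform(0.1, 0.9, size=(5, 6, 4, 3)))


@pytest.fixture(scope="session")
def toy_basis(toy_stack):
    return rgb2dpca.fit_basis(toy_stack)


@pytest.fixture(scope="session")
def phantom_params() -> synthetic.SyntheticParams:
    return synthetic.SyntheticParams(
        height=32, width=32, n_pairs=6, seed=11, center_jitter=3.0,
        semi_axis_range=(4.0, 8.0),
    )


@pytest.fixture(scope="session")
def phantom_ds(phantom_params):
    return synthetic.generate_dataset(phantom_params)


@pytest.fixture(scope="session")
def phantom_basis(phantom_ds):
    return rgb2dpca.fit_basis(phantom_ds.conv)
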