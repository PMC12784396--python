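import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_pools():
    """Moment-matched pools drawn from the default preset table."""
    from hemoscape.bootpca import ReadoutPools
    from hemoscape.synthetic_data import generate_pools

    return ReadoutPools.from_frame(generate_pools(seed=101))


@pytest.fixture(scope="session")
def balanced_image():
    """One synthetic field with 100 cells at a 50% apoptotic fraction."""
    from hemoscape.synthetic_data import SyntheticImageSpec, generate_image

    spec = SyntheticImageSpec(n_cells=100, apoptotic_fraction=0.5, seed=42)
    nuclei, neun, casp3, truth = generate_image(spec)
    return spec, nuclei, neun, casp3, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
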