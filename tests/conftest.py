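import numpy as np
import pytest

from fedseg3d.phantoms import PhantomSpec, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """16^3 phantom with the smallest workable nested-tumor geometry."""
    return PhantomSpec(
        volume_shape=(16, 16, 16),
        tumor_center=(8.0, 8.0, 8.0),
        region_radii=(1.5, 3.0, 5.0),
        noise_sd=0.05,
        seed=7,
    )


@pytest.fixture
def small_case(small_spec):
    return generate_case(small_spec, case_id="fix-0")


def random_label_map(rng, shape=(8, 8, 8)):
    """Random valid {0,1,2,4} label map (no geometric structure implied)."""
    return rng.choice([0, 1, 2, 4], size=shape).astype(np.int16)
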