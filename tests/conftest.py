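import numpy as np
import pytest

from relmap3d import phantoms


@pytest.fixture(scope="session")
def small_atlas():
    return phantoms.build_atlas(grid=16, n_regions=6, seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    return phantoms.generate_cohort(
        n_per_class=6,
        grid=16,
        atlas=small_atlas,
        lesion_spec=phantoms.LesionSpec(regions=(2,), effect=0.4),
        noise_sd=0.05,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
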