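import numpy as np
import pytest

from cinefcn.phantom import PhantomParams, generate_phantom

# Small short-axis phantom geometry used across the suite: 64 x 64 grid at
# 3 mm in-plane spacing, 2 slices, 8 frames.  Noiseless by default so truth
# regions are exact level sets.
SMALL_KW = dict(
    shape=(64, 64, 2, 8),
    spacing_mm=(3.0, 3.0, 10.0),
    lv_radius_ed_mm=18.0,
    myo_thickness_mm=6.0,
    rv_offset_mm=28.0,
    rv_radius_mm=18.0,
    noise_sigma=0.0,
    blur_sigma_mm=0.0,
)


def small_params(**overrides) -> PhantomParams:
    kw = dict(SMALL_KW)
    kw.update(overrides)
    return PhantomParams(**kw)


@pytest.fixture(scope="session")
def small_case():
    return generate_phantom(small_params(seed=7))


@pytest.fixture(scope="session")
def training_cases():
    """Three noiseless phantoms with mildly varied geometry."""
    return [
        generate_phantom(
            small_params(seed=i, ejection_fraction=0.5 + 0.05 * i,
                         lv_radius_ed_mm=17.0 + i)
        )
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def held_out_case():
    return generate_phantom(
        small_params(seed=99, ejection_fraction=0.55, lv_radius_ed_mm=16.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
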