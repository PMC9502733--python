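import numpy as np
import pytest

from ploidycal import ImageSceneSpec, SampleSpec


@pytest.fixture(scope="session")
def small_cohort():
    """Five paired samples, quick to analyze, with the default 1:2 structure."""
    from ploidycal import generate_cohort

    return generate_cohort(5, SampleSpec(n_cells=800, seed=42))


@pytest.fixture(scope="session")
def zero_noise_scene():
    """A rendered noise-free, gradient-free scene with per-object truth."""
    from ploidycal import generate_image_sample

    spec = SampleSpec(n_cells=50, cv=0.0, frac_4N=0.25, frac_debris=0.1, seed=5)
    scene = ImageSceneSpec(image_size=(480, 480), noise_sd=0.0,
                           background_gradient=0.0, seed=2)
    return generate_image_sample(spec, scene)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
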