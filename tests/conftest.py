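import numpy as np
import pytest

from carotidseg.pseudo_rgb import build_slice_dataset
from carotidseg.synthetic import PhantomSpec, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """One deterministic default phantom (16 slices, 32×32)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with circular sections at integer centres."""
    return generate_phantom(PhantomSpec(
        seed=3, noise_sigma=0.0, centerline_wobble_amp=0.0,
        bulge_elongation=1.0, bbox_jitter_px=0))


@pytest.fixture(scope="session")
def small_dataset():
    """Six phantoms with varied contrast, plus their slice pairs."""
    samples = generate_dataset(6, PhantomSpec(), contrast_range=(0.05, 0.30),
                               seed=11)
    pairs = build_slice_dataset(
        [(s.volume, s.weak, f"v{i}") for i, s in enumerate(samples)])
    return samples, pairs


@pytest.fixture
def rng():
    return np.random.default_rng(0)
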