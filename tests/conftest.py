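import numpy as np
import pytest

from hepafuse.synthetic import CohortSpec, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_phantom_spec():
    """64x64 slice with a single mid-size tumor; cheap to rasterize."""
    return PhantomSpec(height=64, width=64, n_tumors=1, radius_range=(6, 12),
                       eccentricity_range=(0.0, 0.4), boundary_irregularity=0.2,
                       tumor_contrast=0.35, background_texture_scale=8.0,
                       noise_sigma=0.05, seed=99)


@pytest.fixture
def tiny_cohort_spec():
    return CohortSpec(n_samples=60, n_markers=40, latent_rank=4, n_subtypes=3,
                      cluster_separation=6.0, marker_noise_sigma=0.5, seed=7)


def numerical_gradient(tensor, func, eps=1e-6):
    """Central-difference gradient of ``func()`` w.r.t. ``tensor.data``."""
    grad = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = tensor.data[idx]
        tensor.data[idx] = orig + eps
        fp = func()
        tensor.data[idx] = orig - eps
        fm = func()
        tensor.data[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad
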