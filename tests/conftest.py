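"""Shared fixtures: small synthetic phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def circular_diff_deg(a: float, b: float, period: float = 180.0) -> float:
    """Smallest absolute difference between two axial angles."""
    d = abs(a - b) % period
    return min(d, period - d)


@pytest.fixture(scope="session")
def linear_cartilage():
    """Cartilage phantom with a linear 2 -> 12 % depth density target."""
    from situtomo.synthetic import CartilagePhantomSpec, gen_cartilage_phantom

    targets = np.linspace(2.0, 12.0, 10)
    spec = CartilagePhantomSpec(
        shape=(120, 96, 96),
        depth_density_profile=tuple(targets),
        noise_sd=0.05,
        seed=4,
    )
    vol, label = gen_cartilage_phantom(spec)
    return vol, label, targets


@pytest.fixture(scope="session")
def delta_fiber():
    """Noisy fiber phantom with all fibers at azimuth 45, elevation 30."""
    from situtomo.synthetic import FiberPhantomSpec, gen_fiber_phantom

    spec = FiberPhantomSpec(
        shape=(64, 64, 64),
        n_fibers=15,
        azimuth_deg=("delta", 45.0),
        elevation_deg=("delta", 30.0),
        noise_sd=0.2,
        seed=2,
    )
    return gen_fiber_phantom(spec)


@pytest.fixture(scope="session")
def delta_fiber_field(delta_fiber):
    from situtomo.meniscus import structure_tensor_orientation

    vol, truth = delta_fiber
    return vol, truth, structure_tensor_orientation(vol)


@pytest.fixture(scope="session")
def smooth_random_volume():
    """Featureful smooth random volume for registration tests."""
    from scipy import ndimage

    from situtomo.io_core import Volume3D

    rng = np.random.default_rng(11)
    data = ndimage.gaussian_filter(rng.normal(size=(48, 48, 48)), 2.0).astype(np.float32)
    data /= data.std()
    return Volume3D(data=data)
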