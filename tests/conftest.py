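"""Shared fixtures: compact phantoms sized for CPU unit tests."""

import numpy as np
import pytest

from cspine.phantom import PhantomSpec, VertebraSpec, generate_phantom


def small_levels(n: int = 7, radii=(10.0, 8.0, 6.0), dz: float = 14.5,
                 z0: float = 14.0, center_xy=(32.0, 32.0)):
    return tuple(
        VertebraSpec(center=(center_xy[0], center_xy[1], z0 + dz * k),
                     radii=radii, has_ring=k < 2)
        for k in range(n))


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """7 vertebrae in a 64-cube at (1, 1, 1.8) mm — fast to rasterize."""
    return PhantomSpec(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.8),
                       levels=small_levels(), body_radius_mm=26.0, seed=3)


@pytest.fixture(scope="session")
def small_sample(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def fractured_sample():
    """Same geometry with a displaced cortical defect at C4."""
    from dataclasses import replace

    from cspine.phantom import FractureSpec
    levels = list(small_levels())
    levels[3] = replace(levels[3], fracture=FractureSpec(
        present=True, angular_width_deg=90.0, displacement_mm=2.0,
        angle_deg=30.0))
    spec = PhantomSpec(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.8),
                       levels=tuple(levels), body_radius_mm=26.0, seed=4)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
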