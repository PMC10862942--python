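import numpy as np
import pytest
from hypothesis import settings

from smpci import Geometry, ProjectedObject

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def bench_geometry() -> Geometry:
    """The experimental layout: 60 cm propagation, 55 um pixels, 20 keV."""
    return Geometry(z=0.6, p=55e-6, nx=96, ny=4, energy=20.0, s=32)


@pytest.fixture
def small_geometry() -> Geometry:
    return Geometry(z=0.6, p=55e-6, nx=32, ny=4, energy=20.0, s=16)


def empty_beam(geometry: Geometry) -> ProjectedObject:
    shape = (geometry.ny * geometry.s, geometry.nx * geometry.s)
    return ProjectedObject(
        dx=geometry.fine_dx,
        dy=geometry.fine_dx,
        T=np.ones(shape),
        phi=np.zeros(shape),
    )


@pytest.fixture
def empty(small_geometry) -> ProjectedObject:
    return empty_beam(small_geometry)
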