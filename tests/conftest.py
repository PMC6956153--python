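import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from onlenspower import (
    CornealModel,
    LensDesignSpec,
    LoadCase,
    build_lens,
    get_material,
)

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def h64():
    return get_material("H64p0-Clear")


@pytest.fixture(scope="session")
def h77():
    return get_material("H77p0-Clear")


@pytest.fixture(scope="session")
def cornea():
    return CornealModel()


@pytest.fixture(scope="session")
def loads():
    return LoadCase()


@pytest.fixture(scope="session")
def plus5_lens(h64):
    """A +5 D spherical lens at full grid resolution."""
    return build_lens(LensDesignSpec(sph=5.0, refractive_index=h64.refractive_index))


@pytest.fixture(scope="session")
def small_lens(h64):
    """A coarse-grid +3 D lens for cheap conformance/trace tests."""
    return build_lens(
        LensDesignSpec(
            sph=3.0,
            refractive_index=h64.refractive_index,
            n_meridians=90,
            n_radial=61,
        )
    )


@pytest.fixture(scope="session")
def toric_lens(h64):
    """A -3/-1 x 90 toric lens at moderate resolution."""
    return build_lens(
        LensDesignSpec(
            sph=-3.0,
            cyl=-1.0,
            cyl_axis=90.0,
            refractive_index=h64.refractive_index,
            n_meridians=180,
            n_radial=81,
        )
    )


@pytest.fixture()
def rigid_material(h64):
    import dataclasses

    return dataclasses.replace(h64, modulus=1e12)


@pytest.fixture()
def floppy_material(h64):
    import dataclasses

    return dataclasses.replace(h64, modulus=1e-12)


def original_arc_lengths(lens) -> float:
    """Meridional polyline arc length of an undeformed back surface."""
    return float(np.hypot(np.diff(lens.x), np.diff(lens.zb)).sum())
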