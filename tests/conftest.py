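"""Shared fixtures: a reduced-size phantom keeps protocol tests fast."""

import numpy as np
import pytest

import resptrack as rt


@pytest.fixture(scope="session")
def small_config() -> rt.PhantomConfig:
    """Coarse phantom: fewer vertices and a coarser mask grid."""
    return rt.PhantomConfig(
        external_subdivisions=4,
        lung_subdivisions=2,
        tumor_subdivisions=2,
        voxel_spacing=(4.0, 4.0, 5.0),
        grid_origin=(-15.0, -85.0, -115.0),
        grid_shape=(38, 43, 54),
    )


@pytest.fixture(scope="session")
def small_source(small_config) -> rt.PhantomSource:
    return rt.PhantomSource(small_config)


@pytest.fixture(scope="session")
def cycle1() -> rt.CycleSpec:
    return rt.TABLE_CYCLES[1]


@pytest.fixture(scope="session")
def small_phantom(small_source, cycle1) -> rt.Phantom4D:
    return small_source.fraction(1, with_masks=True)


def random_composite(rng: np.random.Generator, dim: int, J: int,
                     M: int, N: int, variant: str = "SurphaMod"):
    """Random centered composite matrix for algebra tests."""
    d = rng.normal(size=(dim, J))
    mean = d.mean(axis=1)
    return rt.CompositeMatrix(
        D=d - mean[:, None], mean=mean,
        n_internal_vertices=M, n_patches=N, variant=variant,
    )
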