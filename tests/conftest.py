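import dataclasses

import numpy as np
import pytest

from corridorprobe import HUVolume, PhantomSpec
from corridorprobe.phantom_gen import HULevel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def constant_volume():
    """16^3 volume of constant 100 HU, 1 mm isotropic, origin at 0."""
    return HUVolume(values=np.full((16, 16, 16), 100.0), affine=np.eye(4))


def make_empty_volume(extent_mm, spacing=2.0, value=0.0, origin=None):
    """Axis-aligned constant volume covering [origin, origin+extent] mm."""
    extent = np.asarray(extent_mm, dtype=float)
    origin = np.asarray(origin if origin is not None else -0.25 * extent, dtype=float)
    n = np.ceil(extent / spacing).astype(int) + 1
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin
    return HUVolume(values=np.full(tuple(n), value), affine=affine)


def noise_free(spec: PhantomSpec) -> PhantomSpec:
    """Same phantom spec with every HU noise SD set to zero."""
    levels = {k: HULevel(v.mean, 0.0) for k, v in spec.hu_levels.items()}
    return dataclasses.replace(spec, hu_levels=levels)


@pytest.fixture
def straight_tube_spec():
    return noise_free(PhantomSpec(
        chord_length_mm=60.0, sagitta_mm=0.0, inner_radius_mm=6.0,
        spacing_mm=(1.0, 1.0, 1.0),
    ))
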