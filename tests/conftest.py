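"""Shared fixtures: reduced-geometry phantoms that keep tests fast.

The small geometry (32 slices x 192 axial x 96 lateral, 3 mm field,
5.2 um axial pitch) preserves every structural feature of the native cube —
ten bands, pit, crater, misalignment — at roughly 1/100 the voxel count.
"""

import numpy as np
import pytest

from fovecast import PhantomSpec, RigidTransform, make_phantom_case

SMALL_GEOMETRY = dict(
    n_slices=32,
    n_axial=192,
    n_lateral=96,
    scan_width_um=3000.0,
    axial_pitch_um=5.2,
    pit_width_um=800.0,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(noise_sd=0.0, **SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def small_case(small_spec):
    """A noise-free, identity-aligned small phantom pair."""
    return make_phantom_case(small_spec)


@pytest.fixture(scope="session")
def misaligned_case():
    """A noise-free small phantom with a known rigid misalignment."""
    spec = PhantomSpec(
        noise_sd=0.0,
        misalignment=RigidTransform.from_euler_deg((1.5, -0.8, 1.0), (20.0, 8.0, -35.0)),
        **SMALL_GEOMETRY,
    )
    return make_phantom_case(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
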