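"""Shared fixtures: sphere samplings and small study-condition phantoms.

Heavy objects are session-scoped so the orientation/ODF machinery runs once
per phantom. Phantom sizes are desk-scale (64–120 voxels per side at 1 μm)
so the full suite stays fast while every stage still sees realistic content.
"""

import numpy as np
import pytest

from fiberarch import (
    PhantomSpec,
    compute_structure_tensor,
    generate_phantom,
    principal_orientation,
)
from fiberarch.sphere import build_sphere


@pytest.fixture(scope="session")
def sphere6500():
    return build_sphere(6500)


@pytest.fixture(scope="session")
def sphere_small():
    return build_sphere(1500)


def orientation_of(volume, voxel_um=1.0):
    T = compute_structure_tensor(volume, voxel_um)
    return principal_orientation(T, voxel_um)


@pytest.fixture(scope="session")
def bundled_clean():
    """Noise-free, jitter-free bundle along +z: ground truth is exact."""
    spec = PhantomSpec(
        motif="bundled", shape=(64, 64, 64), seed=5, angular_jitter_deg=0.0,
        noise_sd=0.0, background_level=0.0, volume_fill_target=0.2,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def bundled80():
    return generate_phantom(PhantomSpec(motif="bundled", shape=(80, 80, 80), seed=8))


@pytest.fixture(scope="session")
def meshwork80():
    return generate_phantom(PhantomSpec(motif="meshwork", shape=(80, 80, 80), seed=8))


@pytest.fixture(scope="session")
def laminar80():
    return generate_phantom(
        PhantomSpec(motif="laminar", shape=(80, 80, 80), seed=8, laminar_period=20.0)
    )


@pytest.fixture(scope="session")
def bundled80_field(bundled80):
    return orientation_of(bundled80.volume)


@pytest.fixture(scope="session")
def meshwork80_field(meshwork80):
    return orientation_of(meshwork80.volume)


@pytest.fixture(scope="session")
def laminar80_field(laminar80):
    return orientation_of(laminar80.volume)


@pytest.fixture(scope="session")
def laminar120_result():
    """Full pipeline on a 120³ laminar phantom (λ = 30 μm), one 100³ block."""
    from fiberarch.pipeline import PipelineConfig, run_pipeline

    spec = PhantomSpec(motif="laminar", shape=(120, 120, 120), seed=2, laminar_period=30.0)
    cfg = PipelineConfig(phantom=spec, block_size=100, block_origin=(10, 10, 10))
    return run_pipeline(cfg)
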