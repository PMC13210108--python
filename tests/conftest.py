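"""Shared fixtures: small, fast phantoms reused across test modules.

Phantom grids use 0.4 mm voxels with 2x refinement; fine enough to
resolve 0.3 mm displacement thresholds while keeping each examination
under a few seconds.
"""

import numpy as np
import pytest
import trimesh

from aneupulse.pipeline import RunConfig, run_examination
from aneupulse.synthetic import PhantomSpec, generate_phantom

FAST = dict(voxel_spacing=0.4, sac_radius=3.0, parent_radius=1.5, sac_center=(0.0, 0.0, 4.0))


@pytest.fixture(scope="session")
def fast_config():
    return RunConfig(refine=2)


@pytest.fixture(scope="session")
def static_spec():
    return PhantomSpec(**FAST, n_phases=6, seed=11)


@pytest.fixture(scope="session")
def static_volumes(static_spec):
    return generate_phantom(static_spec)


@pytest.fixture(scope="session")
def global_pulse_report(fast_config):
    """Examination with 2% global radial pulsation and mild boundary noise."""
    spec = PhantomSpec(
        **FAST, n_phases=20, global_pulsation_fraction=0.02, boundary_noise_sd=0.05, seed=7
    )
    return run_examination(generate_phantom(spec), fast_config)


@pytest.fixture(scope="session")
def focal_report(fast_config):
    """Examination with one focal pulsating patch and no global pulsation."""
    spec = PhantomSpec(
        **FAST,
        n_phases=20,
        focal_patch={"center_direction": (0, 0, 1), "angular_radius": 1.2, "extra_amplitude": 0.5},
        seed=3,
    )
    return run_examination(generate_phantom(spec), fast_config)


@pytest.fixture(scope="session")
def static_report(static_volumes, fast_config):
    return run_examination(static_volumes, fast_config)


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
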