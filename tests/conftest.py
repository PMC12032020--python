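import numpy as np
import pytest

from gradmosaic import (
    PlantedGradientSpec,
    make_multimodal_dataset,
    make_parcellation,
    make_sphere_mesh,
)


@pytest.fixture(scope="session")
def mesh():
    """Level-3 icosphere, both hemispheres (1284 vertices total)."""
    return make_sphere_mesh(3, radius=100.0, hemispheres=2)


@pytest.fixture(scope="session")
def mesh_one_hemi():
    return make_sphere_mesh(2, radius=100.0, hemispheres=1)


@pytest.fixture(scope="session")
def atlas(mesh):
    return make_parcellation(mesh, n_areas=40, softness=0.0, seed=11)


@pytest.fixture(scope="session")
def dataset_high_snr(mesh):
    """Low-noise synthetic dataset shared across tests."""
    spec = PlantedGradientSpec(
        seed=7, snr_per_modality={"mpc": 8.0, "sc": 8.0, "fc": 8.0}
    )
    return make_multimodal_dataset(
        mesh, spec, n_tasks=3, n_timepoints=150, n_areas=40
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
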