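"""Shared fixtures: small, coarse synthetic anatomies kept session-scoped so
the geometry-heavy tests reuse them."""

import numpy as np
import pytest
import trimesh

from morphodetail.mesh_core import normalize_volume
from morphodetail.synthetic_anatomy import (AnatomySpec, CohortSpec,
                                            draw_cohort_specs, generate_shape)


@pytest.fixture(scope="session")
def bent_spec() -> AnatomySpec:
    return AnatomySpec(seed=3, bend_angle=80.0, n_lobes=2,
                       detail_amplitude=0.4, detail_frequency=1.0,
                       mesh_resolution=1.0)


@pytest.fixture(scope="session")
def bent_mesh(bent_spec) -> trimesh.Trimesh:
    return generate_shape(bent_spec)


@pytest.fixture(scope="session")
def smooth_mesh(bent_spec) -> trimesh.Trimesh:
    return generate_shape(bent_spec.smooth_counterpart())


@pytest.fixture(scope="session")
def unit_cube() -> trimesh.Trimesh:
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def icosphere() -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=4, radius=2.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six coarse, volume-normalized anatomies with labels."""
    specs = draw_cohort_specs(CohortSpec(n_shapes=6, mesh_resolution=1.2,
                                         master_seed=4))
    meshes = [normalize_volume(generate_shape(s)) for s in specs]
    labels = np.array([s.label for s in specs])
    return meshes, labels


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
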