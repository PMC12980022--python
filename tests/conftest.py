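"""Shared fixtures: all synthetic, generated at session scope."""

import numpy as np
import pytest

from spineplan.camera import look_at_camera
from spineplan.phantom import PhantomParams, generate_vertebra, path_axes, \
    sample_population
from spineplan.ssm import build_ssm_from_meshes


@pytest.fixture(scope="session")
def phantom_params():
    return PhantomParams()


@pytest.fixture(scope="session")
def phantom(phantom_params):
    return generate_vertebra(phantom_params)


@pytest.fixture(scope="session")
def phantom_axes(phantom_params):
    return path_axes(phantom_params)


@pytest.fixture(scope="session")
def population():
    """Small phantom population for model-building tests."""
    meshes, params = sample_population(6, seed=42)
    return meshes, params


@pytest.fixture(scope="session")
def small_model(population):
    """SSM with path annotations, shared by registration/planning tests."""
    meshes, params = population
    model, full_ev = build_ssm_from_meshes(
        meshes, k=4, path_endpoints=path_axes(params[0]))
    return model, full_ev


@pytest.fixture(scope="session")
def two_cameras():
    return [look_at_camera(np.zeros(3), az, 0.0) for az in (0.0, 90.0)]
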