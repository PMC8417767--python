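"""Shared fixtures: synthetic surface pairs, helmets, and helper meshes."""

import numpy as np
import pytest

from orientmeg.forward import fit_sphere
from orientmeg.fixtures import make_cortical_pair, make_helmet
from orientmeg.mesh_core import TriangleMesh, decimate_pair


@pytest.fixture(scope="session")
def folded_pair():
    """Folded pial/white pair at reduced resolution (642 vertices)."""
    return make_cortical_pair(subdivisions=3, seed=7)


@pytest.fixture(scope="session")
def folded_decimated(folded_pair):
    return decimate_pair(folded_pair, 10.0)


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric-sphere pair: the analytic limit (zero fold amplitude)."""
    return make_cortical_pair(subdivisions=4, fold_amplitude_mm=0.0, seed=0)


@pytest.fixture(scope="session")
def sphere_decimated(sphere_pair):
    return decimate_pair(sphere_pair, 10.0)


@pytest.fixture(scope="session")
def helmet_small():
    """60-sensor helmet for fast forward/inverse unit tests."""
    return make_helmet(n_sensors=60)


@pytest.fixture(scope="session")
def helmet_full():
    return make_helmet()


@pytest.fixture(scope="session")
def sphere_center(folded_decimated):
    dec, _ = folded_decimated
    center, _ = fit_sphere(dec.pial.vertices)
    return center


@pytest.fixture(scope="session")
def strip_mesh():
    """Triangle strip whose bottom row is a straight 1 mm-spaced chain.

    The top row sits far away so graph geodesics between bottom-row vertices
    run along the chain with exactly integer millimetre distances.
    """
    n = 11
    bottom = np.column_stack([np.arange(n, dtype=float),
                              np.zeros(n), np.zeros(n)])
    top = np.column_stack([np.arange(n, dtype=float) + 0.5,
                           np.full(n, 100.0), np.zeros(n)])
    verts = np.vstack([bottom, top])
    faces = []
    for i in range(n - 1):
        faces.append([i, i + 1, n + i])
        faces.append([i + 1, n + i + 1, n + i])
    return TriangleMesh(verts, np.array(faces))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
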