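import numpy as np
import pytest

from thermopmi.geometry import generate_phantom
from thermopmi.materials import MaterialTable


@pytest.fixture(scope="session")
def materials():
    return MaterialTable()


@pytest.fixture(scope="session")
def coarse_phantom():
    """Ellipsoid phantom at 2 cm cubes — the desk-scale study geometry."""
    cloud, grid = generate_phantom(shape="ellipsoid", dimensions=(0.3, 0.15, 0.1),
                                   cube_size=0.02)
    return cloud, grid


@pytest.fixture(scope="session")
def cube_surface_cloud():
    """Dense sampling of a 0.2 m axis-aligned cube surface, nudged 1e-6 m
    inward so every point lies in the half-open solid [0, 0.2)^3."""
    side, eps, step = 0.2, 1e-6, 0.002
    u = np.arange(eps, side, step)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    flat = np.stack([uu.ravel(), vv.ravel()], axis=1)
    faces = []
    for axis in range(3):
        for value in (eps, side - eps):
            pts = np.empty((len(flat), 3))
            pts[:, axis] = value
            pts[:, [a for a in range(3) if a != axis]] = flat
            faces.append(pts)
    return np.concatenate(faces, axis=0)
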