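import numpy as np
import pytest
import trimesh

import viewplan as vp


def sphere_cloud(n: int, radius: float, seed: int = 0) -> vp.SurfaceCloud:
    """Uniform points on a sphere with exact radial (outward) normals."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return vp.SurfaceCloud(points=radius * u, normals=u)


def plane_cloud(n_side: int, extent: float, seed: int = 0) -> vp.SurfaceCloud:
    """Jittered grid in the z=0 plane, normals +z."""
    rng = np.random.default_rng(seed)
    g = np.linspace(-extent, extent, n_side)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    pts[:, :2] += rng.normal(0, 0.05 * (g[1] - g[0]), (len(pts), 2))
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return vp.SurfaceCloud(points=pts, normals=normals)


def cylinder_cloud(n: int, radius: float, length: float,
                   seed: int = 0) -> vp.SurfaceCloud:
    """Lateral surface of a cylinder along z, outward radial normals."""
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-length / 2, length / 2, n)
    normals = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), z])
    return vp.SurfaceCloud(points=pts, normals=normals)


def sphere_mesh(radius: float = 1.0, subdivisions: int = 3) -> vp.SurfaceMesh:
    return vp.SurfaceMesh.from_trimesh(
        trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius))


@pytest.fixture(scope="session")
def organ_mesh() -> vp.SurfaceMesh:
    return vp.default_fixture(seed=0)


@pytest.fixture(scope="session")
def organ_cloud(organ_mesh) -> vp.SurfaceCloud:
    return vp.mesh_to_cloud(organ_mesh, 2000, seed=1)


@pytest.fixture(scope="session")
def organ_landmarks(organ_mesh) -> vp.LandmarkSet:
    return vp.generate_landmarks(organ_mesh, seed=2)


@pytest.fixture(scope="session")
def organ_cloud_curv(organ_cloud) -> vp.SurfaceCloud:
    return vp.attach_curvature(organ_cloud)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
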