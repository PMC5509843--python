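import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

import viewplan as vp
from conftest import sphere_cloud, sphere_mesh


def random_transform(seed: int) -> vp.RigidTransform:
    rng = np.random.default_rng(seed)
    return vp.RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                             rng.uniform(-50, 50, 3))


class TestRigidTransform:
    def test_rejects_reflection_and_non_orthonormal(self):
        with pytest.raises(ValueError):
            vp.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            vp.RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_compose_inverse_roundtrip(self, rng):
        t = random_transform(7)
        pts = rng.uniform(-30, 30, (50, 3))
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_preserves_pairwise_distances(self, seed):
        t = random_transform(seed)
        pts = np.random.default_rng(seed).uniform(-40, 40, (30, 3))
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        moved = t.apply(pts)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)


class TestSurfaceIO:
    @pytest.mark.parametrize("ext", ["ply", "stl", "obj"])
    def test_save_load_roundtrip(self, tmp_path, ext):
        mesh = sphere_mesh(radius=7.5, subdivisions=2)
        path = tmp_path / f"m.{ext}"
        vp.save_surface(mesh, path)
        again = vp.load_surface(path)
        assert again.n_faces == mesh.n_faces
        # STL duplicates vertices per-facet; compare sorted coordinates sets
        tree = cKDTree(mesh.vertices)
        d, _ = tree.query(again.vertices, k=1)
        assert d.max() < 1e-4

    def test_icosphere_ply_counts(self, tmp_path):
        tm = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
        path = tmp_path / "ico.ply"
        tm.export(path)
        mesh = vp.load_surface(path)
        assert mesh.n_vertices == 42
        assert mesh.n_faces == 80

    def test_single_triangle_stl(self, tmp_path):
        tm = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                             faces=[[0, 1, 2]], process=False)
        path = tmp_path / "tri.stl"
        tm.export(path)
        mesh = vp.load_surface(path)
        assert mesh.n_vertices == 3
        assert mesh.n_faces == 1

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "broken.ply"
        path.write_bytes(b"ply\nformat binary_little_endian 1.0\n"
                         b"element vertex 9999\n")
        with pytest.raises((IOError, ValueError)):
            vp.load_surface(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            vp.load_surface(tmp_path / "nope.ply")

    def test_cloud_ply_roundtrip_with_curvature(self, tmp_path):
        cloud = sphere_cloud(100, 5.0)
        cloud = vp.SurfaceCloud(points=cloud.points, normals=cloud.normals,
                                gaussian_curvature=np.full(100, 0.04))
        path = tmp_path / "c.ply"
        vp.save_cloud(cloud, path)
        again = vp.load_cloud(path)
        np.testing.assert_allclose(again.points, cloud.points, atol=1e-8)
        np.testing.assert_allclose(again.gaussian_curvature, 0.04)


class TestMeshToCloud:
    def test_points_on_sphere_surface(self):
        mesh = sphere_mesh(radius=10.0, subdivisions=4)
        cloud = vp.mesh_to_cloud(mesh, 1000, seed=3)
        r = np.linalg.norm(cloud.points, axis=1)
        # facet chord error bound for subdivision-4 icosphere
        assert np.all(np.abs(r - 10.0) < 0.05)
        assert len(cloud) == 1000

    def test_deterministic_per_seed(self, organ_mesh):
        a = vp.mesh_to_cloud(organ_mesh, 500, seed=9)
        b = vp.mesh_to_cloud(organ_mesh, 500, seed=9)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.normals, b.normals)

    def test_rejects_zero_points(self, organ_mesh):
        with pytest.raises(ValueError):
            vp.mesh_to_cloud(organ_mesh, 0, seed=0)

    def test_uniform_area_nn_spacing(self):
        # Poisson-process mean NN distance on the unit sphere:
        # 0.5 * sqrt(4 pi / n)
        n = 100_000
        mesh = sphere_mesh(radius=1.0, subdivisions=5)
        cloud = vp.mesh_to_cloud(mesh, n, seed=4)
        d, _ = cKDTree(cloud.points).query(cloud.points, k=2)
        expected = 0.5 * np.sqrt(4 * np.pi / n)
        assert abs(d[:, 1].mean() - expected) / expected < 0.20


class TestNormalize:
    def test_already_normalized_identity(self):
        # exactly centred cloud (antipodal pairs) with max norm exactly 1
        half = sphere_cloud(100, 1.0)
        cloud = vp.SurfaceCloud(points=np.vstack([half.points, -half.points]),
                                normals=np.vstack([half.normals,
                                                   -half.normals]))
        out, scale, center = vp.normalize_to_unit_sphere(cloud)
        assert scale == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(center, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.points, cloud.points, atol=1e-9)

    def test_offset_cloud(self):
        base = sphere_cloud(300, 5.0)
        cloud = vp.SurfaceCloud(points=base.points + [10.0, 0, 0],
                                normals=base.normals)
        out, scale, center = vp.normalize_to_unit_sphere(cloud)
        np.testing.assert_allclose(out.centroid, 0.0, atol=1e-12)
        assert np.linalg.norm(out.points, axis=1).max() <= 1.0 + 1e-9

    def test_denormalize_roundtrip(self, organ_cloud):
        out, scale, center = vp.normalize_to_unit_sphere(organ_cloud)
        back = vp.denormalize(out, scale, center)
        np.testing.assert_allclose(back.points, organ_cloud.points, atol=1e-9)

    def test_empty_cloud_rejected(self):
        empty = vp.SurfaceCloud(points=np.zeros((0, 3)),
                                normals=np.zeros((0, 3)))
        with pytest.raises(ValueError):
            vp.normalize_to_unit_sphere(empty)


def brute_force_voxel_count(points: np.ndarray, voxel: float) -> int:
    """Independent grid-hash oracle for occupied voxel count."""
    return len({tuple(np.floor(p / voxel).astype(int)) for p in points})


class TestDownsample:
    def test_tiny_voxel_is_identity(self):
        cloud = sphere_cloud(200, 10.0)
        out = vp.downsample(cloud, 1e-4)
        assert len(out) == len(cloud)

    def test_cube_corners_collapse(self):
        corners = np.array([[x, y, z] for x in (0, 1.0) for y in (0, 1.0)
                            for z in (0, 1.0)])
        normals = np.tile([0, 0, 1.0], (8, 1))
        out = vp.downsample(vp.SurfaceCloud(points=corners, normals=normals),
                            10.0)
        assert len(out) == 1
        np.testing.assert_allclose(out.points[0], [0.5, 0.5, 0.5])

    def test_matches_grid_hash_oracle(self, rng):
        pts = rng.uniform(-40, 40, (10_000, 3))
        n = rng.normal(size=(10_000, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        cloud = vp.SurfaceCloud(points=pts, normals=n)
        for voxel in (3.0, 7.5):
            out = vp.downsample(cloud, voxel)
            assert len(out) == brute_force_voxel_count(pts, voxel)

    def test_idempotent(self, organ_cloud):
        once = vp.downsample(organ_cloud, 4.0)
        twice = vp.downsample(once, 4.0)
        assert len(twice) == len(once)

    def test_rejects_nonpositive_voxel(self, organ_cloud):
        with pytest.raises(ValueError):
            vp.downsample(organ_cloud, 0.0)


class TestApplyTransform:
    def test_identity_unchanged(self, organ_cloud):
        out = vp.apply_transform(vp.RigidTransform.identity(), organ_cloud)
        np.testing.assert_array_equal(out.points, organ_cloud.points)

    def test_pure_translation(self, organ_cloud):
        t = vp.RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
        out = vp.apply_transform(t, organ_cloud)
        np.testing.assert_allclose(
            out.points - organ_cloud.points,
            np.tile([1.0, 2.0, 3.0], (len(organ_cloud), 1)), atol=1e-12)
        np.testing.assert_array_equal(out.normals, organ_cloud.normals)

    def test_inverse_roundtrip(self, organ_cloud):
        t = random_transform(11)
        out = vp.apply_transform(t.inverse().compose(t), organ_cloud)
        np.testing.assert_allclose(out.points, organ_cloud.points, atol=1e-9)
        np.testing.assert_allclose(out.normals, organ_cloud.normals,
                                   atol=1e-9)
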