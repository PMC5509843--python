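"""Mesh / point-cloud data model shared by every stage of the pipeline.

All geometry is expressed in millimetres in a right-handed frame.  The
unit-sphere normalisation used to place the camera sphere never leaks into
registration or error metrics, which always work in the original mm frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "SurfaceCloud",
    "RigidTransform",
    "load_surface",
    "save_surface",
    "mesh_to_cloud",
    "save_cloud",
    "load_cloud",
    "normalize_to_unit_sphere",
    "denormalize",
    "downsample",
    "apply_transform",
]

_NORMAL_TOL = 1e-6


def _as_points(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"{name} must be an (N, 3) array, got shape {a.shape}")
    return a


def _check_unit(normals: np.ndarray, tol: float = _NORMAL_TOL) -> None:
    norms = np.linalg.norm(normals, axis=1)
    if not np.allclose(norms, 1.0, atol=tol):
        bad = np.abs(norms - 1.0).max()
        raise ValueError(f"normals must be unit length (max deviation {bad:.2e})")


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated closed surface with outward per-vertex normals."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray

    def __post_init__(self):
        v = _as_points(self.vertices, "vertices")
        f = np.asarray(self.faces, dtype=np.int64)
        n = _as_points(self.normals, "normals")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] == 0:
            raise ValueError("faces must be a non-empty (M, 3) index array")
        if f.min() < 0 or f.max() >= len(v):
            raise ValueError("face indices out of vertex range")
        if len(n) != len(v):
            raise ValueError("one normal per vertex required")
        _check_unit(n)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        object.__setattr__(self, "normals", n)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        normals = _outward_vertex_normals(tm)
        return cls(vertices=np.asarray(tm.vertices, dtype=float),
                   faces=np.asarray(tm.faces, dtype=np.int64),
                   normals=normals)


@dataclass(frozen=True)
class SurfaceCloud:
    """Oriented point cloud: positions + unit normals (+ optional curvature).

    Houses the fixed model P_f, the simulated camera patches P_m, and the
    merged maximum visible surface P_max.
    """

    points: np.ndarray
    normals: np.ndarray
    gaussian_curvature: np.ndarray | None = None
    source_viewpoint: int | None = None

    def __post_init__(self):
        p = _as_points(self.points, "points")
        n = _as_points(self.normals, "normals")
        if len(p) != len(n):
            raise ValueError("points and normals must have equal length")
        if len(p):
            _check_unit(n)
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "normals", n)
        if self.gaussian_curvature is not None:
            k = np.asarray(self.gaussian_curvature, dtype=float)
            if k.shape != (len(p),):
                raise ValueError("gaussian_curvature must be per-point scalar")
            object.__setattr__(self, "gaussian_curvature", k)

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_idx, source_viewpoint: int | None = None
               ) -> "SurfaceCloud":
        """Pure selection of a subset; curvature values travel with points."""
        k = self.gaussian_curvature
        return SurfaceCloud(
            points=self.points[mask_or_idx],
            normals=self.normals[mask_or_idx],
            gaussian_curvature=None if k is None else k[mask_or_idx],
            source_viewpoint=(self.source_viewpoint
                              if source_viewpoint is None else source_viewpoint),
        )

    @property
    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise ValueError("empty cloud has no centroid")
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class RigidTransform:
    """6-DoF rotation + translation, p -> R p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (R R^T = I)")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation determinant must be +1 (no reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_pivot(cls, rotation: np.ndarray, translation,
                    pivot) -> "RigidTransform":
        """Rotation about `pivot` followed by `translation`:
        p -> R (p - pivot) + pivot + t."""
        rotation = np.asarray(rotation, dtype=float)
        pivot = np.asarray(pivot, dtype=float).reshape(3)
        t = np.asarray(translation, dtype=float).reshape(3)
        return cls(rotation, pivot - rotation @ pivot + t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def apply_normals(self, normals: np.ndarray) -> np.ndarray:
        return np.asarray(normals, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _outward_vertex_normals(tm: trimesh.Trimesh) -> np.ndarray:
    """Per-vertex normals oriented outward by majority vote against the centroid."""
    n = np.asarray(tm.vertex_normals, dtype=float).copy()
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    n /= norms
    radial = tm.vertices - tm.vertices.mean(axis=0)
    vote = np.sign(np.einsum("ij,ij->i", radial, n)).sum()
    if vote < 0:
        n = -n
    return n


def load_surface(path, file_format: str | None = None) -> SurfaceMesh:
    """Load a triangulated surface (PLY / STL / OBJ) as a :class:`SurfaceMesh`.

    Outward per-vertex normals are recomputed from the faces; a mesh with no
    faces is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load_mesh(str(path), file_type=file_format)
    except Exception as exc:  # noqa: BLE001 - surface format zoo
        raise IOError(f"could not parse mesh file {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise ValueError(f"mesh file {path} contains no geometry")
        tm = trimesh.util.concatenate(geoms)
    if tm.faces is None or len(tm.faces) == 0:
        raise ValueError(f"degenerate mesh (0 faces): {path}")
    return SurfaceMesh.from_trimesh(tm)


def save_surface(mesh: SurfaceMesh, path) -> None:
    mesh.to_trimesh().export(str(path))


def mesh_to_cloud(mesh: SurfaceMesh, n_points: int, seed: int) -> SurfaceCloud:
    """Uniform-area sample of the surface with face-normal orientation.

    Deterministic for a fixed seed; normals are taken from the sampled face
    (flat interpolation), oriented to agree with the mesh's outward vertex
    normals.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    tm = mesh.to_trimesh()
    rng = np.random.default_rng(seed)
    # uniform-area sampling: pick faces ~ area, then uniform barycentric coords
    areas = tm.area_faces
    face_idx = rng.choice(len(areas), size=n_points, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n_points))
    r2 = rng.random(n_points)
    tri = tm.triangles[face_idx]
    pts = ((1 - r1)[:, None] * tri[:, 0]
           + (r1 * (1 - r2))[:, None] * tri[:, 1]
           + (r1 * r2)[:, None] * tri[:, 2])
    fn = np.asarray(tm.face_normals, dtype=float)[face_idx]
    # align face normals with the outward vertex-normal field
    ref = mesh.normals[mesh.faces[face_idx, 0]]
    flip = np.einsum("ij,ij->i", fn, ref) < 0
    fn[flip] *= -1
    fn /= np.linalg.norm(fn, axis=1, keepdims=True)
    return SurfaceCloud(points=pts, normals=fn)


def save_cloud(cloud: SurfaceCloud, path) -> None:
    """Write an ascii PLY with x,y,z,nx,ny,nz (+ `quality` = Gaussian curvature)."""
    path = Path(path)
    has_k = cloud.gaussian_curvature is not None
    props = ["property double x", "property double y", "property double z",
             "property double nx", "property double ny", "property double nz"]
    if has_k:
        props.append("property double quality")
    header = ["ply", "format ascii 1.0",
              f"element vertex {len(cloud)}", *props, "end_header"]
    cols = [cloud.points, cloud.normals]
    if has_k:
        cols.append(cloud.gaussian_curvature[:, None])
    data = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, data, fmt="%.10g")


def load_cloud(path) -> SurfaceCloud:
    """Read a PLY point cloud with x,y,z,nx,ny,nz (and optional quality)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cloud file not found: {path}")
    with open(path, "rb") as fh:
        header = []
        while True:
            line = fh.readline().decode("ascii", errors="replace").strip()
            header.append(line)
            if line == "end_header":
                break
            if len(header) > 100:
                raise IOError(f"not a PLY file: {path}")
        names = [h.split()[-1] for h in header if h.startswith("property")]
        n = int(next(h.split()[-1] for h in header if h.startswith("element vertex")))
        data = np.loadtxt(fh, max_rows=n)
    data = np.atleast_2d(data)
    col = {name: i for i, name in enumerate(names)}
    for req in ("x", "y", "z", "nx", "ny", "nz"):
        if req not in col:
            raise IOError(f"PLY {path} lacks required property {req!r}")
    pts = data[:, [col["x"], col["y"], col["z"]]]
    nrm = data[:, [col["nx"], col["ny"], col["nz"]]]
    k = data[:, col["quality"]] if "quality" in col else None
    return SurfaceCloud(points=pts, normals=nrm, gaussian_curvature=k)


def normalize_to_unit_sphere(cloud: SurfaceCloud
                             ) -> tuple[SurfaceCloud, float, np.ndarray]:
    """Centre at the centroid and isotropically scale to fit the unit sphere.

    Returns (normalised cloud, scale, center) such that
    ``original = normalised * scale + center``.
    """
    if len(cloud) == 0:
        raise ValueError("cannot normalise an empty cloud")
    center = cloud.centroid
    shifted = cloud.points - center
    scale = float(np.linalg.norm(shifted, axis=1).max())
    if scale == 0.0:
        scale = 1.0
    out = replace(cloud, points=shifted / scale)
    return out, scale, center


def denormalize(cloud: SurfaceCloud, scale: float, center) -> SurfaceCloud:
    center = np.asarray(center, dtype=float).reshape(3)
    return replace(cloud, points=cloud.points * scale + center)


def downsample(cloud: SurfaceCloud, voxel_size: float) -> SurfaceCloud:
    """Voxel-grid downsampling: one centroid per occupied voxel.

    Normals are averaged and renormalised; curvature values averaged.  The
    output lies inside the input's bounding box by construction.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    if len(cloud) == 0:
        return cloud
    keys = np.floor(cloud.points / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True,
                                   return_counts=True)
    n_vox = len(counts)

    def _mean(values: np.ndarray) -> np.ndarray:
        out = np.zeros((n_vox, values.shape[1]))
        np.add.at(out, inverse, values)
        return out / counts[:, None]

    pts = _mean(cloud.points)
    nrm = _mean(cloud.normals)
    lens = np.linalg.norm(nrm, axis=1, keepdims=True)
    # a voxel whose normals cancel exactly keeps its first point's normal
    degenerate = lens[:, 0] < 1e-12
    if degenerate.any():
        first = np.full(n_vox, -1, dtype=np.int64)
        for i, v in enumerate(inverse):
            if first[v] < 0:
                first[v] = i
        nrm[degenerate] = cloud.normals[first[degenerate]]
        lens = np.linalg.norm(nrm, axis=1, keepdims=True)
    nrm /= lens
    k = cloud.gaussian_curvature
    k_out = None if k is None else _mean(k[:, None])[:, 0]
    return SurfaceCloud(points=pts, normals=nrm, gaussian_curvature=k_out,
                        source_viewpoint=cloud.source_viewpoint)


def apply_transform(t: RigidTransform, cloud: SurfaceCloud) -> SurfaceCloud:
    """Map points by R p + t and normals by R n."""
    return replace(cloud, points=t.apply(cloud.points),
                   normals=t.apply_normals(cloud.normals))
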