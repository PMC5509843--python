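"""Organ-like synthetic surfaces with controllable flat and bumpy regions.

The fixture stands in for a segmented pre-operative CT organ model: a closed,
asymmetric, liver-scale surface that contains both near-flat (ambiguous) and
high-curvature (distinctive) regions, plus an interior landmark cluster that
plays the role of a simulated abnormality for target-registration-error
measurement.

The surface is a radial graph over the unit sphere of directions: an
ellipsoid radius field, perturbed by Gaussian radial bumps, with one spherical
cap replaced by a plane (the flat patch).  Radial graphs are star-shaped, so
the mesh is watertight and self-intersection free by construction as long as
the radius stays positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import SurfaceMesh, _outward_vertex_normals

__all__ = ["FixtureSpec", "LandmarkSet", "generate_organ_mesh",
           "generate_landmarks", "default_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic organ surface.

    Defaults are liver-scale: semi-axes (60, 45, 35) mm, 12 bumps of 6 mm
    amplitude, and one flat cap covering 15% of the sphere of directions —
    enough curvature contrast for viewpoint scoring to be meaningful.
    """

    base_radii: tuple[float, float, float] = (60.0, 45.0, 35.0)
    n_bumps: int = 12
    bump_amplitude: float = 6.0
    bump_width: float = 0.35        # angular scale, radians
    flat_patch_fraction: float = 0.15
    seed: int = 0
    subdivisions: int = 4           # icosphere subdivision level

    def __post_init__(self):
        if any(r <= 0 for r in self.base_radii):
            raise ValueError("base_radii must be positive")
        if not (0.0 <= self.flat_patch_fraction < 1.0):
            raise ValueError("flat_patch_fraction must be in [0, 1)")
        if self.bump_amplitude < 0:
            raise ValueError("bump_amplitude must be >= 0")
        if self.n_bumps < 0:
            raise ValueError("n_bumps must be >= 0")


@dataclass(frozen=True)
class LandmarkSet:
    """Interior points used only for error measurement, never registration."""

    points: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or len(p) == 0:
            raise ValueError("landmarks must be a non-empty (N, 3) array")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return len(self.points)


def points_inside(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Ray-parity (even-odd) containment test against a closed mesh.

    Casts one ray per query point along a fixed irrational direction and
    counts Möller–Trumbore triangle crossings; an odd count means inside.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.vertices[mesh.faces]                    # (M, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    d = np.array([0.5773502691896258, 0.5773502691896257, 0.5773502691896259])
    pvec = np.cross(d, e2)                             # (M, 3)
    det = np.einsum("ij,ij->i", e1, pvec)              # (M,)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    inside = np.zeros(len(pts), dtype=bool)
    for i, o in enumerate(pts):
        tvec = o - v0                                  # (M, 3)
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        v = (qvec @ d) * inv_det
        t = np.einsum("ij,ij->i", e2, qvec) * inv_det
        hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        inside[i] = bool(hits.sum() % 2)
    return inside


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _ellipsoid_radius(u: np.ndarray, radii) -> np.ndarray:
    a, b, c = radii
    return 1.0 / np.sqrt((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2
                         + (u[:, 2] / c) ** 2)


def generate_organ_mesh(spec: FixtureSpec) -> SurfaceMesh:
    """Deterministically build the bumpy-ellipsoid-with-flat-cap fixture.

    With ``n_bumps=0``, ``flat_patch_fraction=0`` and equal radii the output
    is an exact sphere (degenerate case used by the curvature oracle tests).
    """
    base = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    u = np.asarray(base.vertices, dtype=float)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    rng = np.random.default_rng(spec.seed)

    r = _ellipsoid_radius(u, spec.base_radii)

    # flat cap: fixed +x axis so the flat face sits on the longest semi-axis
    cap_axis = np.array([1.0, 0.0, 0.0])
    if spec.flat_patch_fraction > 0.0:
        cos_alpha = 1.0 - 2.0 * spec.flat_patch_fraction
        alpha = np.arccos(np.clip(cos_alpha, -1.0, 1.0))
        ang = np.arccos(np.clip(u @ cap_axis, -1.0, 1.0))
        band = 0.15 * alpha                     # smooth blend band at the rim
        cap_w = _smoothstep((alpha - ang) / band)
    else:
        alpha = 0.0
        cap_w = np.zeros(len(u))

    if spec.n_bumps > 0 and spec.bump_amplitude > 0:
        # bump centres uniform on the sphere, kept clear of the flat cap
        dirs = []
        while len(dirs) < spec.n_bumps:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            if spec.flat_patch_fraction > 0.0 and \
                    np.arccos(np.clip(d @ cap_axis, -1, 1)) < alpha + spec.bump_width:
                continue
            dirs.append(d)
        dirs = np.array(dirs)
        signs = rng.choice([-1.0, 1.0], size=spec.n_bumps, p=[0.3, 0.7])
        ang2 = np.arccos(np.clip(u @ dirs.T, -1.0, 1.0)) ** 2
        bump = (signs * np.exp(-ang2 / (2.0 * spec.bump_width ** 2))).sum(axis=1)
        r = r + spec.bump_amplitude * bump * (1.0 - cap_w)

    if spec.flat_patch_fraction > 0.0:
        # plane perpendicular to the cap axis at the truncation depth
        d_plane = _ellipsoid_radius(cap_axis[None, :], spec.base_radii)[0] \
            * np.cos(alpha)
        cos_ang = np.clip(u @ cap_axis, 1e-6, 1.0)
        r_flat = d_plane / cos_ang
        r = (1.0 - cap_w) * r + cap_w * r_flat

    if (r <= 0).any():
        raise ValueError("fixture radius field went non-positive; "
                         "reduce bump_amplitude")
    tm = trimesh.Trimesh(vertices=u * r[:, None], faces=base.faces,
                         process=False)
    return SurfaceMesh(vertices=np.asarray(tm.vertices),
                       faces=np.asarray(tm.faces),
                       normals=_outward_vertex_normals(tm))


def default_fixture(seed: int = 0) -> SurfaceMesh:
    """The default liver-scale fixture at the given seed."""
    return generate_organ_mesh(FixtureSpec(seed=seed))


def generate_landmarks(mesh: SurfaceMesh, n: int = 20,
                       offset=(20.0, 0.0, 0.0), radius: float = 5.0,
                       seed: int = 0) -> LandmarkSet:
    """Sample ``n`` landmarks uniformly in an interior ball.

    Emulates a simulated abnormality inside the organ.  The ball
    ``sphere(offset, radius)`` must lie strictly inside the closed surface;
    every sampled point is additionally verified with a ray-parity
    containment test.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    offset = np.asarray(offset, dtype=float).reshape(3)
    # the ball must be strictly interior: check the centre and boundary probes
    probes = offset[None, :] + radius * np.vstack(
        [np.zeros(3), np.eye(3), -np.eye(3)])
    if not points_inside(mesh, probes).all():
        raise ValueError("landmark ball is not strictly inside the surface")
    rng = np.random.default_rng(seed)
    if radius == 0.0:
        pts = np.tile(offset, (n, 1))
    else:
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        rr = radius * rng.random(n) ** (1.0 / 3.0)
        pts = offset + v * rr[:, None]
    inside = points_inside(mesh, pts)
    if not inside.all():
        raise ValueError("sampled landmarks fall outside the surface")
    return LandmarkSet(points=pts)
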