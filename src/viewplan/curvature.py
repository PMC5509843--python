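"""Principal-curvature estimation and curvature-based viewpoint scoring.

Each point's neighbourhood is fitted with an osculating paraboloid (quadric
height function over the tangent plane defined by the point's normal); the
principal curvatures k1 >= k2 of the fitted surface give the Gaussian
curvature K = k1 * k2.  Sign convention: convex-outward regions have
k1, k2 > 0, so a dome has K > 0, a saddle K < 0 and a plane or cylinder
K = 0.

A viewpoint's score is the mean Gaussian curvature over its visible patch,

    f_surface = sum_i K_i / N ,

which separates ambiguous (flat, featureless) patches from distinctive
(high-curvature) ones.  Because signed saddle contributions cancel convex
ones, the default scoring variant averages |K_i| instead; the signed mean
remains available as ``variant='raw'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .geometry import SurfaceCloud

__all__ = ["CurvatureField", "PatchScore", "estimate_curvatures",
           "attach_curvature", "mean_spacing", "score_patch",
           "rank_viewpoints", "select_patches"]

MIN_PATCH_SIZE = 50
_MIN_NEIGHBOURS = 6     # quadric has 6 coefficients


@dataclass(frozen=True)
class CurvatureField:
    """Per-point principal curvatures (mm^-1) and Gaussian curvature (mm^-2).

    Points whose neighbourhood was too starved for a stable quadric fit are
    flagged invalid and carry NaN curvatures.
    """

    k1: np.ndarray
    k2: np.ndarray
    gaussian: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        if not (len(self.k1) == len(self.k2) == len(self.gaussian)
                == len(self.valid)):
            raise ValueError("curvature arrays must have equal length")


@dataclass(frozen=True)
class PatchScore:
    """Ranking unit: one viewpoint's f_surface value and patch size."""

    viewpoint_id: int
    f_surface: float
    n_points: int
    variant: str


def mean_spacing(cloud: SurfaceCloud) -> float:
    """Mean nearest-neighbour distance, the cloud's natural length scale."""
    if len(cloud) < 2:
        raise ValueError("need at least two points")
    tree = cKDTree(cloud.points)
    d, _ = tree.query(cloud.points, k=2)
    return float(d[:, 1].mean())


def _local_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit tangent vectors orthogonal to `normal`."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def estimate_curvatures(cloud: SurfaceCloud,
                        neighbourhood_radius: float | None = None
                        ) -> CurvatureField:
    """Fit a quadric height function per point and return its curvatures.

    ``neighbourhood_radius`` defaults to 4x the mean point spacing.  A point
    with fewer than 6 neighbours in its ball is flagged invalid; if more than
    20% of points are invalid a warning is emitted (the cloud is too sparse
    for the chosen radius).
    """
    n = len(cloud)
    if n < _MIN_NEIGHBOURS:
        raise ValueError("cloud too small for curvature estimation")
    if neighbourhood_radius is None:
        neighbourhood_radius = 4.0 * mean_spacing(cloud)
    if neighbourhood_radius <= 0:
        raise ValueError("neighbourhood_radius must be > 0")

    tree = cKDTree(cloud.points)
    neighbour_lists = tree.query_ball_point(cloud.points, neighbourhood_radius)

    k1 = np.full(n, np.nan)
    k2 = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    pts = cloud.points
    nrm = cloud.normals
    for i in range(n):
        idx = neighbour_lists[i]
        if len(idx) < _MIN_NEIGHBOURS:
            continue
        normal = nrm[i]
        e1, e2 = _local_frame(normal)
        rel = pts[idx] - pts[i]
        x = rel @ e1
        y = rel @ e2
        h = rel @ normal
        # h(x, y) = a x^2 + b x y + c y^2 + d x + e y + f
        A = np.column_stack([x * x, x * y, y * y, x, y, np.ones(len(idx))])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        a, b, c, d, e, _f = coef
        # first/second fundamental forms of the graph (x, y, h(x, y)) at 0
        w2 = 1.0 + d * d + e * e
        w = np.sqrt(w2)
        E, F, G = 1.0 + d * d, d * e, 1.0 + e * e
        L, M, N = 2.0 * a / w, b / w, 2.0 * c / w
        K = (L * N - M * M) / (E * G - F * F)
        H = (E * N - 2.0 * F * M + G * L) / (2.0 * (E * G - F * F))
        disc = max(H * H - K, 0.0)
        root = np.sqrt(disc)
        # the height axis is the outward normal; the graph curvatures are
        # negative on a convex-outward dome, so flip to make domes positive
        ka, kb = -(H - root), -(H + root)
        k1[i], k2[i] = max(ka, kb), min(ka, kb)
        valid[i] = True

    invalid_frac = 1.0 - valid.mean()
    if invalid_frac > 0.20:
        warnings.warn(
            f"{invalid_frac:.0%} of points have starved curvature "
            "neighbourhoods; consider a larger radius", stacklevel=2)
    return CurvatureField(k1=k1, k2=k2, gaussian=k1 * k2, valid=valid)


def attach_curvature(cloud: SurfaceCloud,
                     neighbourhood_radius: float | None = None) -> SurfaceCloud:
    """Return a copy of ``cloud`` carrying per-point Gaussian curvature."""
    field = estimate_curvatures(cloud, neighbourhood_radius)
    return replace(cloud, gaussian_curvature=field.gaussian)


def score_patch(patch: SurfaceCloud, variant: str = "absolute",
                min_patch_size: int = MIN_PATCH_SIZE) -> PatchScore:
    """Mean (or mean-absolute) Gaussian curvature of a visible patch."""
    if variant not in ("raw", "absolute"):
        raise ValueError("variant must be 'raw' or 'absolute'")
    if patch.gaussian_curvature is None:
        raise ValueError("patch has no curvature values; run attach_curvature")
    k = patch.gaussian_curvature
    k = k[np.isfinite(k)]
    if len(k) < min_patch_size:
        vid = patch.source_viewpoint
        raise ValueError(
            f"patch from viewpoint {vid} has only {len(k)} valid curvature "
            f"points (min_patch_size={min_patch_size})")
    value = float(np.abs(k).mean() if variant == "absolute" else k.mean())
    return PatchScore(
        viewpoint_id=-1 if patch.source_viewpoint is None
        else patch.source_viewpoint,
        f_surface=value, n_points=len(k), variant=variant)


def rank_viewpoints(scores: list[PatchScore]) -> list[PatchScore]:
    """Descending by f_surface; ties by larger patch, then smaller id."""
    if not scores:
        raise ValueError("no scores to rank")
    return sorted(scores,
                  key=lambda s: (-s.f_surface, -s.n_points, s.viewpoint_id))


def select_patches(ranked: list[PatchScore], strategy: str, k: int,
                   seed: int = 0) -> list[int]:
    """Pick ``k`` viewpoint ids from a ranked score list.

    ``highest``: the k best scores; ``lowest``: the k worst; ``random``:
    a seeded uniform draw without replacement.
    """
    if k > len(ranked) or k < 1:
        raise ValueError(f"k={k} out of range for {len(ranked)} viewpoints")
    if strategy == "highest":
        chosen = ranked[:k]
    elif strategy == "lowest":
        chosen = ranked[-k:][::-1]
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        chosen = [ranked[i] for i in rng.choice(len(ranked), size=k,
                                                replace=False)]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return [s.viewpoint_id for s in chosen]
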