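"""Simulated visible surface patches.

Emulates what a laparoscope at a viewpoint would reconstruct: the organ point
cloud is culled to the camera-facing surface (back-face test on normals),
optionally restricted to a field-of-view cone and refined with spherical-flip
hidden-point removal (HPR) to drop points occluded by concavities, which
normal-only culling leaks.  The default is back-face culling only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .camera import ViewpointSample
from .geometry import SurfaceCloud, downsample

__all__ = ["VisibilityConfig", "visible_patch", "max_visible_surface"]


@dataclass(frozen=True)
class VisibilityConfig:
    """How visibility is decided: ``backface`` or ``backface+hpr``, plus an
    optional field-of-view half-angle (degrees)."""

    mode: str = "backface"
    fov_half_angle: float | None = None
    hpr_radius_factor: float = 3.0

    def __post_init__(self):
        if self.mode not in ("backface", "backface+hpr"):
            raise ValueError("mode must be 'backface' or 'backface+hpr'")
        if self.fov_half_angle is not None and not (0 < self.fov_half_angle <= 90):
            raise ValueError("fov_half_angle must be in (0, 90] degrees")
        if self.hpr_radius_factor <= 1.0:
            raise ValueError("hpr_radius_factor must exceed 1")


def _hpr_mask(points: np.ndarray, camera: np.ndarray, radius_factor: float
              ) -> np.ndarray:
    """Spherical-flip hidden-point removal (Katz-style).

    Points are reflected through a sphere centred at the camera; the visible
    set is whatever lands on the convex hull of the flipped cloud plus the
    camera itself.
    """
    if len(points) < 5:
        return np.ones(len(points), dtype=bool)
    rel = points - camera
    d = np.linalg.norm(rel, axis=1)
    radius = radius_factor * d.max()
    flipped = rel + 2.0 * (radius - d)[:, None] * rel / d[:, None]
    pts = np.vstack([flipped, np.zeros(3)])
    try:
        hull = ConvexHull(pts)
    except Exception:       # degenerate (coplanar) clouds: keep everything
        return np.ones(len(points), dtype=bool)
    mask = np.zeros(len(pts), dtype=bool)
    mask[hull.vertices] = True
    return mask[:-1]


def _patch_mask(cloud: SurfaceCloud, vp: ViewpointSample,
                cfg: VisibilityConfig) -> np.ndarray:
    to_cam = vp.position - cloud.points
    # strict inequality: grazing points (normal orthogonal to ray) excluded
    mask = np.einsum("ij,ij->i", cloud.normals, to_cam) > 0.0
    if cfg.fov_half_angle is not None:
        ray = -to_cam
        ray_n = np.linalg.norm(ray, axis=1)
        ray_n[ray_n == 0] = 1.0
        cosang = (ray @ vp.view_direction) / ray_n
        mask &= cosang >= np.cos(np.radians(cfg.fov_half_angle))
    if cfg.mode == "backface+hpr" and mask.any():
        idx = np.flatnonzero(mask)
        sub = _hpr_mask(cloud.points[idx], vp.position, cfg.hpr_radius_factor)
        keep = np.zeros(len(cloud), dtype=bool)
        keep[idx[sub]] = True
        mask = keep
    return mask


def visible_patch(cloud: SurfaceCloud, vp: ViewpointSample,
                  cfg: VisibilityConfig = VisibilityConfig()) -> SurfaceCloud:
    """Select the subset of ``cloud`` visible from ``vp``.

    Back-face cull keeps points with normal · (camera − point) strictly
    positive; an optional FOV cone and HPR pass restrict further.  The result
    is a pure selection of the input with ``source_viewpoint`` set; an empty
    patch is returned as such (the caller decides whether that is an error).
    """
    if len(cloud) == 0:
        raise ValueError("cannot render from an empty cloud")
    return cloud.select(_patch_mask(cloud, vp, cfg), source_viewpoint=vp.id)


def max_visible_surface(cloud: SurfaceCloud, viewpoints: list[ViewpointSample],
                        cfg: VisibilityConfig = VisibilityConfig(),
                        voxel_size: float = 2.0) -> SurfaceCloud:
    """Merge the patches of all viewpoints into the maximum visible surface.

    The union is deduplicated (each source point appears once however many
    viewpoints see it) and voxel-downsampled.
    """
    if not viewpoints:
        raise ValueError("at least one viewpoint required")
    union = np.zeros(len(cloud), dtype=bool)
    for vp in viewpoints:
        union |= _patch_mask(cloud, vp, cfg)
    if not union.any():
        raise ValueError("all patches empty: no visible surface")
    return downsample(cloud.select(union, source_viewpoint=None), voxel_size)
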