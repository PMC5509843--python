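"""Trocar-constrained spherical camera space.

The laparoscope is modelled as a camera on a virtual sphere around the organ,
always looking at the organ centre, parametrised by spherical coordinates
(radius r, longitude theta, colatitude phi, degrees).  The trocar pins the
centre of the allowed motion range; clinicians provide half-ranges around it.
Camera roll is ignored: visibility and curvature scoring are roll-invariant
once the optical axis points at the centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SphericalCoord", "CameraConstraint", "ViewpointSample",
           "spherical_to_cartesian", "cartesian_to_spherical",
           "sample_viewpoints"]


def _wrap_theta(theta: float) -> float:
    return float((theta + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class SphericalCoord:
    """(r, theta, phi): radius mm, longitude deg, colatitude deg (0 = +z pole)."""

    r: float
    theta: float
    phi: float

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("radius must be > 0")
        if not (0.0 <= self.phi <= 180.0):
            raise ValueError("colatitude phi must be in [0, 180] degrees")
        object.__setattr__(self, "theta", _wrap_theta(self.theta))


@dataclass(frozen=True)
class CameraConstraint:
    """Motion range (r_c ± Δr, θ_c ± Δθ, φ_c ± Δφ) around the trocar pose."""

    center: SphericalCoord
    delta_r: float = 0.0
    delta_theta: float = 0.0
    delta_phi: float = 0.0

    def __post_init__(self):
        if min(self.delta_r, self.delta_theta, self.delta_phi) < 0:
            raise ValueError("deltas must be >= 0")
        if self.center.r - self.delta_r <= 0:
            raise ValueError("radius range must stay positive")

    @property
    def phi_range(self) -> tuple[float, float]:
        return (max(0.0, self.center.phi - self.delta_phi),
                min(180.0, self.center.phi + self.delta_phi))

    @property
    def theta_range(self) -> tuple[float, float]:
        return (self.center.theta - self.delta_theta,
                self.center.theta + self.delta_theta)

    @property
    def r_range(self) -> tuple[float, float]:
        return (self.center.r - self.delta_r, self.center.r + self.delta_r)


@dataclass(frozen=True)
class ViewpointSample:
    """A camera pose: spherical coordinate + derived position and axis."""

    coord: SphericalCoord
    position: np.ndarray
    view_direction: np.ndarray
    id: int

    def __post_init__(self):
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float).reshape(3))
        object.__setattr__(self, "view_direction",
                           np.asarray(self.view_direction, dtype=float).reshape(3))


def spherical_to_cartesian(c: SphericalCoord, centre=(0.0, 0.0, 0.0)) -> np.ndarray:
    """centre + r (sinφ cosθ, sinφ sinθ, cosφ)."""
    centre = np.asarray(centre, dtype=float).reshape(3)
    th = np.radians(c.theta)
    ph = np.radians(c.phi)
    return centre + c.r * np.array([np.sin(ph) * np.cos(th),
                                    np.sin(ph) * np.sin(th),
                                    np.cos(ph)])


def cartesian_to_spherical(p, centre=(0.0, 0.0, 0.0)) -> SphericalCoord:
    v = np.asarray(p, dtype=float).reshape(3) - np.asarray(centre, float).reshape(3)
    r = float(np.linalg.norm(v))
    if r == 0:
        raise ValueError("point coincides with centre")
    phi = float(np.degrees(np.arccos(np.clip(v[2] / r, -1.0, 1.0))))
    theta = float(np.degrees(np.arctan2(v[1], v[0])))
    return SphericalCoord(r=r, theta=theta, phi=phi)


def _make_sample(coord: SphericalCoord, centre: np.ndarray, idx: int
                 ) -> ViewpointSample:
    pos = spherical_to_cartesian(coord, centre)
    view = centre - pos
    view /= np.linalg.norm(view)
    return ViewpointSample(coord=coord, position=pos, view_direction=view, id=idx)


def sample_viewpoints(constraint: CameraConstraint, n, mode: str = "random",
                      seed: int = 0, centre=(0.0, 0.0, 0.0)
                      ) -> list[ViewpointSample]:
    """Sample camera poses inside the constraint box in (r, theta, phi).

    ``mode='random'``: per-coordinate uniform draws, seeded.
    ``mode='grid'``: an evenly spaced theta x phi lattice at fixed r = r_c
    (``n`` may be a total count, squared-rooted, or a ``(n_theta, n_phi)``
    pair); endpoints inclusive.
    """
    centre = np.asarray(centre, dtype=float).reshape(3)
    r_lo, r_hi = constraint.r_range
    t_lo, t_hi = constraint.theta_range
    p_lo, p_hi = constraint.phi_range
    if p_lo > p_hi:
        raise ValueError("empty feasible colatitude range")
    if mode == "random":
        if int(n) < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        rs = rng.uniform(r_lo, r_hi, int(n))
        ts = rng.uniform(t_lo, t_hi, int(n))
        ps = rng.uniform(p_lo, p_hi, int(n))
        coords = [SphericalCoord(r, th, ph) for r, th, ph in zip(rs, ts, ps)]
    elif mode == "grid":
        if isinstance(n, (tuple, list)):
            nt, np_ = int(n[0]), int(n[1])
        else:
            nt = np_ = int(round(np.sqrt(int(n))))
        if nt < 1 or np_ < 1:
            raise ValueError("grid dimensions must be >= 1")
        ts = np.linspace(t_lo, t_hi, nt) if nt > 1 else np.array([constraint.center.theta])
        ps = np.linspace(p_lo, p_hi, np_) if np_ > 1 else np.array([constraint.center.phi])
        coords = [SphericalCoord(constraint.center.r, th, ph)
                  for th in ts for ph in ps]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return [_make_sample(c, centre, i) for i, c in enumerate(coords)]
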