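"""Rigid ICP registration, perturbation sampling, reconstruction noise, TRE.

The registration objective is the classic least-squares alignment

    min_T  sum_i || p_f,c(i) - T(p_m,i) ||^2

between the fixed organ model P_f and a moving simulated patch P_m, solved by
point-to-point iterative closest point: alternate nearest-neighbour
correspondence with the closed-form Umeyama/SVD rigid fit until the
mean-squared error stops improving.

Accuracy is measured as target registration error (TRE) at interior landmark
points that never participate in the registration itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .fixtures import LandmarkSet
from .geometry import RigidTransform, SurfaceCloud

__all__ = ["PerturbationSpec", "NoiseSpec", "IcpConfig", "IcpResult",
           "RegistrationTrial", "sample_perturbation", "add_normal_noise",
           "run_icp", "compute_tre", "classify_convergence"]


@dataclass(frozen=True)
class PerturbationSpec:
    """Uniform per-axis rotation (±deg) and translation (±mm) ranges."""

    rot_range: float = 10.0
    trans_range: float = 10.0
    n_trials: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.rot_range < 0 or self.trans_range < 0:
            raise ValueError("ranges must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Anisotropic reconstruction noise: N(0, sigma mm) along each normal."""

    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class IcpConfig:
    max_iterations: int = 200
    transformation_epsilon: float = 1e-8
    max_correspondence_distance: float | None = None

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class IcpResult:
    transform: RigidTransform
    iterations_used: int
    mse_history: np.ndarray


@dataclass(frozen=True)
class RegistrationTrial:
    """One simulated registration: perturb, recover, measure."""

    perturbation: RigidTransform
    recovered: RigidTransform
    tre: float
    iterations_used: int
    converged_flag: bool

    def __post_init__(self):
        if self.tre < 0:
            raise ValueError("tre must be >= 0")


def sample_perturbation(spec: PerturbationSpec, trial_index: int,
                        pivot=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Draw one random rigid perturbation, deterministic per (seed, index).

    Euler angles (intrinsic x-y-z) uniform in ±rot_range, translation
    components uniform in ±trans_range; the rotation acts about ``pivot``
    (pass the moving cloud's centroid so rotation and translation ranges are
    comparable in effect).
    """
    rng = np.random.default_rng([spec.seed, int(trial_index)])
    angles = rng.uniform(-spec.rot_range, spec.rot_range, 3)
    trans = rng.uniform(-spec.trans_range, spec.trans_range, 3)
    rot = Rotation.from_euler("XYZ", angles, degrees=True).as_matrix()
    return RigidTransform.about_pivot(rot, trans, pivot)


def add_normal_noise(cloud: SurfaceCloud, spec: NoiseSpec) -> SurfaceCloud:
    """Displace each point along its normal by N(0, sigma^2); seeded."""
    if len(cloud) and np.isnan(cloud.normals).any():
        raise ValueError("cloud normals required for along-normal noise")
    if spec.sigma == 0.0:
        return cloud
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.sigma, len(cloud))
    return replace(cloud, points=cloud.points + eps[:, None] * cloud.normals)


def _umeyama_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit mapping src -> dst (no scale)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    cov = (dst - mu_d).T @ (src - mu_s) / len(src)
    U, _S, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    t = mu_d - R @ mu_s
    return RigidTransform(R, t)


def run_icp(fixed: SurfaceCloud, moving: SurfaceCloud,
            cfg: IcpConfig = IcpConfig()) -> IcpResult:
    """Point-to-point ICP aligning ``moving`` onto ``fixed``.

    Returns the rigid transform mapping the moving cloud onto the fixed one
    and the per-iteration mean-squared correspondence error (non-increasing
    by construction of the alternating minimisation).
    """
    if len(fixed) == 0 or len(moving) == 0:
        raise ValueError("both clouds must be non-empty")
    tree = cKDTree(fixed.points)
    current = moving.points.copy()
    transform = RigidTransform.identity()
    mse_prev = np.inf
    history = []
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        dist, nn = tree.query(current, k=1)
        if cfg.max_correspondence_distance is not None:
            keep = dist <= cfg.max_correspondence_distance
            if keep.sum() < 3:
                raise RuntimeError("degenerate correspondence set (< 3 points)")
            step = _umeyama_rigid(current[keep], fixed.points[nn[keep]])
        else:
            if len(current) < 3:
                raise RuntimeError("degenerate correspondence set (< 3 points)")
            step = _umeyama_rigid(current, fixed.points[nn])
        transform = step.compose(transform)
        current = step.apply(current)
        # error of the *current* correspondences after the closed-form step
        mse = float(np.mean(np.sum((fixed.points[nn] - current) ** 2, axis=1)))
        history.append(mse)
        if abs(mse_prev - mse) < cfg.transformation_epsilon:
            break
        mse_prev = mse
    return IcpResult(transform=transform, iterations_used=iterations,
                     mse_history=np.asarray(history))


def compute_tre(landmarks: LandmarkSet, perturbation: RigidTransform,
                recovered: RigidTransform) -> float:
    """Mean landmark error after perturbing then registering back.

    TRE = mean_l || recovered(perturbation(l)) - l ||, in mm.
    """
    if len(landmarks) == 0:
        raise ValueError("landmark set must be non-empty")
    moved = recovered.apply(perturbation.apply(landmarks.points))
    return float(np.linalg.norm(moved - landmarks.points, axis=1).mean())


def classify_convergence(trial: RegistrationTrial,
                         tre_threshold: float = 5.0) -> bool:
    """Success iff TRE <= threshold (boundary inclusive)."""
    return trial.tre <= tre_threshold
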