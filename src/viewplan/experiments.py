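"""The three simulation experiments, as seeded pipelines producing tables.

1. Viewpoint evaluation — sample camera positions on the enclosing sphere,
   render each visible patch, score it by mean Gaussian curvature, and run
   repeated randomly-perturbed ICP registrations to relate score to target
   registration error (TRE).
2. Basin of convergence — compare the lowest-scoring patch P_low, the
   highest-scoring patch P_high and the merged maximum visible surface P_max
   over a grid of single-axis rotations, extracting the contiguous range of
   initial misalignments from which ICP still recovers the pose.
3. Patch count — merge an increasing number of patches chosen by strategy
   (random / lowest / highest score) and track mean TRE against the P_max
   baseline.

All randomness is derived from a single master seed; reruns with identical
configuration are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .camera import CameraConstraint, SphericalCoord, ViewpointSample, \
    sample_viewpoints
from .curvature import PatchScore, attach_curvature, rank_viewpoints, \
    score_patch, select_patches, MIN_PATCH_SIZE
from .fixtures import LandmarkSet
from .geometry import RigidTransform, SurfaceCloud, apply_transform, downsample
from .registration import IcpConfig, NoiseSpec, PerturbationSpec, \
    RegistrationTrial, add_normal_noise, classify_convergence, compute_tre, \
    run_icp, sample_perturbation
from .visibility import VisibilityConfig, _patch_mask, visible_patch

__all__ = ["ExperimentConfig", "ViewpointEvaluationResult", "BasinResult",
           "PatchCountResult", "full_sphere_constraint",
           "run_viewpoint_evaluation", "run_basin_experiment",
           "run_patch_count_experiment"]

_MSE_MONOTONE_TOL = 1e-9


def _subseed(master: int, *tags: int) -> int:
    """Independent, reproducible sub-seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), *map(int, tags)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared knobs: visibility, ICP, scoring and merging behaviour.

    The experiments default to a 30 degree field-of-view half-angle: a
    laparoscope images a limited cone, and without it back-face culling on a
    mostly convex organ returns near-hemispheric "patches", which defeats the
    point of comparing local views.  Pass a ``VisibilityConfig`` with
    ``fov_half_angle=None`` for unbounded views.
    """

    visibility: VisibilityConfig = field(
        default_factory=lambda: VisibilityConfig(fov_half_angle=30.0))
    icp: IcpConfig = field(default_factory=IcpConfig)
    curvature_radius: float | None = None   # None -> 4 x mean spacing
    score_variant: str = "absolute"
    min_patch_size: int = MIN_PATCH_SIZE
    merge_voxel: float = 4.0                # mm, for merged clouds / P_max
    tre_threshold: float = 5.0              # mm, convergence classification
    sphere_radius_factor: float = 1.5       # camera sphere vs bounding radius


def full_sphere_constraint(cloud: SurfaceCloud,
                           radius_factor: float = 1.5) -> CameraConstraint:
    """Unconstrained viewing sphere at radius_factor x the bounding radius."""
    rad = float(np.linalg.norm(cloud.points - cloud.centroid, axis=1).max())
    return CameraConstraint(
        center=SphericalCoord(r=radius_factor * rad, theta=0.0, phi=90.0),
        delta_r=0.0, delta_theta=180.0, delta_phi=90.0)


@dataclass(frozen=True)
class ViewpointEvaluationResult:
    table: pd.DataFrame       # one row per scored viewpoint
    trials: pd.DataFrame      # one row per registration trial
    skipped: tuple            # (viewpoint_id, reason) pairs

    def to_csv(self, table_path, trials_path) -> None:
        self.table.to_csv(table_path, index=False)
        self.trials.to_csv(trials_path, index=False)


@dataclass(frozen=True)
class BasinResult:
    table: pd.DataFrame       # scenario x axis x angle -> tre, converged
    intervals: pd.DataFrame   # scenario x axis -> contiguous interval at 0
    scores: pd.DataFrame      # per-viewpoint scores backing P_low/P_high


@dataclass(frozen=True)
class PatchCountResult:
    table: pd.DataFrame       # strategy x k -> mean/std TRE
    trials: pd.DataFrame


def _check_monotone(history: np.ndarray) -> None:
    if len(history) > 1 and np.any(np.diff(history) > _MSE_MONOTONE_TOL *
                                   max(1.0, history[0])):
        raise AssertionError("ICP objective increased between iterations")


def _perturbed_trial(fixed: SurfaceCloud, moving: SurfaceCloud,
                     landmarks: LandmarkSet, pert: RigidTransform,
                     cfg: ExperimentConfig) -> RegistrationTrial:
    moved = apply_transform(pert, moving)
    res = run_icp(fixed, moved, cfg.icp)
    _check_monotone(res.mse_history)
    tre = compute_tre(landmarks, pert, res.transform)
    trial = RegistrationTrial(perturbation=pert, recovered=res.transform,
                              tre=tre, iterations_used=res.iterations_used,
                              converged_flag=False)
    return RegistrationTrial(perturbation=pert, recovered=res.transform,
                             tre=tre, iterations_used=res.iterations_used,
                             converged_flag=classify_convergence(
                                 trial, cfg.tre_threshold))


def _scored_patches(cloud: SurfaceCloud, viewpoints: list[ViewpointSample],
                    cfg: ExperimentConfig
                    ) -> tuple[SurfaceCloud, dict, list[PatchScore], list]:
    """Attach curvature, render every patch, score the viable ones."""
    if cloud.gaussian_curvature is None:
        cloud = attach_curvature(cloud, cfg.curvature_radius)
    patches: dict[int, SurfaceCloud] = {}
    scores: list[PatchScore] = []
    skipped: list[tuple[int, str]] = []
    for vp in viewpoints:
        patch = visible_patch(cloud, vp, cfg.visibility)
        if len(patch) < cfg.min_patch_size:
            skipped.append((vp.id, f"patch too small ({len(patch)} points)"))
            continue
        patches[vp.id] = patch
        scores.append(score_patch(patch, cfg.score_variant,
                                  cfg.min_patch_size))
    return cloud, patches, scores, skipped


def run_viewpoint_evaluation(cloud: SurfaceCloud, landmarks: LandmarkSet,
                             n_viewpoints: int = 20,
                             perturbation_spec: PerturbationSpec = PerturbationSpec(n_trials=20),
                             noise_spec: NoiseSpec = NoiseSpec(),
                             cfg: ExperimentConfig = ExperimentConfig(),
                             seed: int = 0,
                             constraint: CameraConstraint | None = None
                             ) -> ViewpointEvaluationResult:
    """Experiment 1: relate curvature score to registration error.

    For each sampled viewpoint: render the visible patch, score it, add
    along-normal reconstruction noise, then apply ``n_trials`` random rigid
    perturbations and register back with ICP, recording the landmark TRE of
    every trial.  Viewpoints whose patch is too small are reported as skipped.
    """
    centre = cloud.centroid
    if constraint is None:
        constraint = full_sphere_constraint(cloud, cfg.sphere_radius_factor)
    viewpoints = sample_viewpoints(constraint, n_viewpoints, "random",
                                   _subseed(seed, 1), centre)
    cloud, patches, scores, skipped = _scored_patches(cloud, viewpoints, cfg)
    vp_by_id = {vp.id: vp for vp in viewpoints}

    rows, trial_rows = [], []
    for score in scores:
        vid = score.viewpoint_id
        patch = patches[vid]
        noisy = add_normal_noise(patch, NoiseSpec(
            sigma=noise_spec.sigma, seed=_subseed(seed, 2, vid)))
        pspec = PerturbationSpec(rot_range=perturbation_spec.rot_range,
                                 trans_range=perturbation_spec.trans_range,
                                 n_trials=perturbation_spec.n_trials,
                                 seed=_subseed(seed, 3, vid))
        pivot = noisy.centroid
        tres = []
        for j in range(pspec.n_trials):
            pert = sample_perturbation(pspec, j, pivot)
            trial = _perturbed_trial(cloud, noisy, landmarks, pert, cfg)
            tres.append(trial.tre)
            ang = Rotation.from_matrix(pert.rotation).as_euler("XYZ",
                                                               degrees=True)
            trial_rows.append({
                "viewpoint_id": vid, "trial_id": j,
                "rot_x": ang[0], "rot_y": ang[1], "rot_z": ang[2],
                "t_x": pert.translation[0], "t_y": pert.translation[1],
                "t_z": pert.translation[2], "tre_mm": trial.tre,
                "iterations": trial.iterations_used,
                "converged": trial.converged_flag})
        tres = np.asarray(tres)
        vp = vp_by_id[vid]
        rows.append({
            "viewpoint_id": vid, "theta": vp.coord.theta, "phi": vp.coord.phi,
            "f_surface": score.f_surface, "n_points": score.n_points,
            "mean_tre": tres.mean(), "std_tre": tres.std(ddof=0),
            "log_mean_tre": np.log(tres.mean()),
            "n_trials": pspec.n_trials})
    return ViewpointEvaluationResult(table=pd.DataFrame(rows),
                                     trials=pd.DataFrame(trial_rows),
                                     skipped=tuple(skipped))


def _contiguous_interval(angles: np.ndarray, converged: np.ndarray
                         ) -> tuple[float, float, float]:
    """Maximal contiguous successful angle run containing 0 degrees."""
    order = np.argsort(angles)
    angles, converged = angles[order], converged[order]
    i0 = int(np.argmin(np.abs(angles)))
    if not converged[i0]:
        return (np.nan, np.nan, 0.0)
    lo = i0
    while lo > 0 and converged[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(angles) - 1 and converged[hi + 1]:
        hi += 1
    return (float(angles[lo]), float(angles[hi]),
            float(angles[hi] - angles[lo]))


def run_basin_experiment(cloud: SurfaceCloud, landmarks: LandmarkSet,
                         n_viewpoints: int = 20,
                         angle_range: float = 40.0, n_steps: int = 24,
                         noise_spec: NoiseSpec = NoiseSpec(),
                         cfg: ExperimentConfig = ExperimentConfig(),
                         seed: int = 0,
                         constraint: CameraConstraint | None = None
                         ) -> BasinResult:
    """Experiment 2: ICP basins of convergence for P_low, P_high, P_max.

    The rotation grid covers ±angle_range over ``n_steps`` evenly spaced
    angles (endpoints inclusive), with 0° always evaluated as a sanity
    anchor, for each of the x, y, z axes.  The convergence interval per axis
    is the maximal contiguous successful run containing 0°.
    """
    centre = cloud.centroid
    if constraint is None:
        constraint = full_sphere_constraint(cloud, cfg.sphere_radius_factor)
    viewpoints = sample_viewpoints(constraint, n_viewpoints, "random",
                                   _subseed(seed, 1), centre)
    cloud, patches, scores, _skipped = _scored_patches(cloud, viewpoints, cfg)
    if not scores:
        raise ValueError("no viable patches to build scenarios from")
    ranked = rank_viewpoints(scores)
    scenarios = {
        "P_high": patches[ranked[0].viewpoint_id],
        "P_low": patches[ranked[-1].viewpoint_id],
    }
    union = np.zeros(len(cloud), dtype=bool)
    for vp in viewpoints:
        union |= _patch_mask(cloud, vp, cfg.visibility)
    scenarios["P_max"] = downsample(cloud.select(union), cfg.merge_voxel)

    grid = np.linspace(-angle_range, angle_range, n_steps)
    if not np.any(np.isclose(grid, 0.0)):
        grid = np.sort(np.append(grid, 0.0))

    rows = []
    for si, (name, patch) in enumerate(scenarios.items()):
        noisy = add_normal_noise(patch, NoiseSpec(
            sigma=noise_spec.sigma, seed=_subseed(seed, 4, si)))
        pivot = noisy.centroid
        for ai, axis in enumerate("xyz"):
            for angle in grid:
                rot = Rotation.from_euler(axis, angle, degrees=True).as_matrix()
                pert = RigidTransform.about_pivot(rot, np.zeros(3), pivot)
                trial = _perturbed_trial(cloud, noisy, landmarks, pert, cfg)
                rows.append({"scenario": name, "axis": axis,
                             "angle_deg": float(angle), "tre_mm": trial.tre,
                             "iterations": trial.iterations_used,
                             "converged": trial.converged_flag})
    table = pd.DataFrame(rows)
    ivals = []
    for name in scenarios:
        for axis in "xyz":
            sub = table[(table.scenario == name) & (table.axis == axis)]
            lo, hi, width = _contiguous_interval(
                sub.angle_deg.to_numpy(), sub.converged.to_numpy())
            ivals.append({"scenario": name, "axis": axis,
                          "interval_lo_deg": lo, "interval_hi_deg": hi,
                          "width_deg": width})
    score_df = pd.DataFrame([{"viewpoint_id": s.viewpoint_id,
                              "f_surface": s.f_surface,
                              "n_points": s.n_points} for s in ranked])
    return BasinResult(table=table, intervals=pd.DataFrame(ivals),
                       scores=score_df)


def run_patch_count_experiment(cloud: SurfaceCloud, landmarks: LandmarkSet,
                               n_viewpoints: int = 20,
                               strategies=("random", "lowest", "highest"),
                               k_max: int = 6,
                               perturbation_spec: PerturbationSpec = PerturbationSpec(n_trials=20),
                               noise_spec: NoiseSpec = NoiseSpec(),
                               cfg: ExperimentConfig = ExperimentConfig(),
                               seed: int = 0,
                               constraint: CameraConstraint | None = None
                               ) -> PatchCountResult:
    """Experiment 3: mean TRE versus number of merged patches per strategy.

    For each strategy and k = 1..k_max the selected patches are merged into
    one moving cloud, perturbed ``n_trials`` times and registered back; the
    P_max merge of all patches serves as the baseline (strategy
    ``baseline_max``).
    """
    centre = cloud.centroid
    if constraint is None:
        constraint = full_sphere_constraint(cloud, cfg.sphere_radius_factor)
    viewpoints = sample_viewpoints(constraint, n_viewpoints, "random",
                                   _subseed(seed, 1), centre)
    cloud, patches, scores, _skipped = _scored_patches(cloud, viewpoints, cfg)
    ranked = rank_viewpoints(scores)
    pool = len(ranked)
    if k_max > pool:
        import warnings
        warnings.warn(f"k_max={k_max} exceeds the {pool}-viewpoint pool; "
                      "truncating", stacklevel=2)
        k_max = pool

    mask_by_id = {vp.id: _patch_mask(cloud, vp, cfg.visibility)
                  for vp in viewpoints if vp.id in patches}

    def _merged(ids: list[int]) -> SurfaceCloud:
        union = np.zeros(len(cloud), dtype=bool)
        for vid in ids:
            union |= mask_by_id[vid]
        return downsample(cloud.select(union), cfg.merge_voxel)

    conditions = [(strategy, k) for strategy in strategies
                  for k in range(1, k_max + 1)]
    conditions.append(("baseline_max", pool))

    rows, trial_rows = [], []
    for ci, (strategy, k) in enumerate(conditions):
        if strategy == "baseline_max":
            ids = [s.viewpoint_id for s in ranked]
        else:
            ids = select_patches(ranked, strategy, k,
                                 seed=_subseed(seed, 5, k))
        moving = _merged(ids)
        noisy = add_normal_noise(moving, NoiseSpec(
            sigma=noise_spec.sigma, seed=_subseed(seed, 6, ci)))
        pspec = PerturbationSpec(rot_range=perturbation_spec.rot_range,
                                 trans_range=perturbation_spec.trans_range,
                                 n_trials=perturbation_spec.n_trials,
                                 seed=_subseed(seed, 7))
        pivot = noisy.centroid
        tres = []
        for j in range(pspec.n_trials):
            pert = sample_perturbation(pspec, j, pivot)
            trial = _perturbed_trial(cloud, noisy, landmarks, pert, cfg)
            tres.append(trial.tre)
            trial_rows.append({"strategy": strategy, "k": k, "trial_id": j,
                               "tre_mm": trial.tre,
                               "iterations": trial.iterations_used,
                               "converged": trial.converged_flag})
        tres = np.asarray(tres)
        rows.append({"strategy": strategy, "k": k,
                     "n_points": len(noisy), "mean_tre": tres.mean(),
                     "std_tre": tres.std(ddof=0),
                     "n_trials": pspec.n_trials})
    return PatchCountResult(table=pd.DataFrame(rows),
                            trials=pd.DataFrame(trial_rows))
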