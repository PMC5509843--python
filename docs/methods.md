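# Methods

## Model and pipeline

`viewplan` studies rigid 3D–3D registration between a fixed organ surface
cloud `P_f` (sampled from a pre-operative CT-style surface mesh) and moving
clouds `P_m` that simulate intra-operative surface reconstructions. The
registration objective is the standard least-squares alignment
`min_T Σ ‖P_f − T(P_m)‖²`, solved with point-to-point iterative closest
point (ICP): alternate nearest-neighbour correspondence (k-d tree on `P_f`)
with the closed-form Umeyama/SVD rigid fit, stopping when the mean-squared
correspondence error improves by less than `transformation_epsilon` or after
`max_iterations`. The per-iteration error is provably non-increasing for
this alternation, and the experiment drivers assert that on every trial.

The planning question is which camera viewpoints yield `P_m` clouds that
register well. The pipeline has five stages:

1. **Camera space.** Viewpoints live on a sphere around the organ,
   parametrised by spherical coordinates (radius r in mm, longitude θ,
   colatitude φ, degrees), always looking at the organ centre. A trocar
   constraint is a central pose with half-ranges (±Δr, ±Δθ, ±Δφ); sampling
   is uniform per coordinate (or an evenly spaced θ×φ lattice). The default
   sphere radius is 1.5× the cloud's bounding radius; Δr defaults to 0,
   reducing the search to 2D. Camera roll is ignored — with the optical
   axis pinned to the centre, visibility and curvature scoring are
   roll-invariant.
2. **Visibility.** The patch a camera would reconstruct is simulated by
   back-face culling: keep points with `n · (c − p) > 0` (strict, so
   grazing points drop out). An optional field-of-view cone and a
   spherical-flip hidden-point-removal (HPR) pass are available; HPR only
   ever removes further points. Merging the patches of all viewpoints in
   the constrained space (deduplicated, voxel-downsampled) gives the
   maximum visible surface `P_max`.
3. **Curvature scoring.** Principal curvatures are estimated per point by
   fitting an osculating paraboloid (quadric height function over the
   tangent plane defined by the point's normal) to the neighbourhood within
   a radius, default 4× the mean nearest-neighbour spacing. The sign
   convention makes convex-outward regions positive. A viewpoint's score is
   `f_surface = Σ Kᵢ / N` over its patch with `K = k₁k₂`; the default
   variant averages |K| because signed saddle (K < 0) and dome (K > 0)
   contributions cancel under the literal signed mean, hiding exactly the
   distinctiveness the score is meant to reward. The signed mean remains
   available as `variant="raw"`. Patches with fewer than 50 valid points
   are not scored.
4. **Perturbation and noise.** Moving clouds receive anisotropic
   reconstruction noise N(0, σ) displacing each point along its normal
   (σ = 1 mm default), and random rigid perturbations with intrinsic
   x→y→z Euler angles uniform in ±10° and translations uniform in ±10 mm,
   rotating about the moving cloud's centroid so rotational and
   translational offsets are comparable in effect.
5. **Error metric.** Target registration error (TRE) is the mean distance
   by which interior landmark points (20 points in a 5 mm ball, offset
   20 mm from the centroid — a simulated abnormality) miss their true
   positions after perturbation and recovery. Landmarks never participate
   in the registration. A trial counts as converged when TRE ≤ 5 mm; the
   threshold is configurable and reported with results.

## The synthetic fixture

No patient geometry ships with the package, so all experiments run on a
generated organ-like surface: a radial graph over an icosphere (subdivision
4, 2562 vertices) whose radius field is an ellipsoid with liver-scale
semi-axes (60, 45, 35) mm, perturbed by 12 Gaussian radial bumps of 6 mm
amplitude and 0.35 rad width (70% outward, 30% inward, seeded directions),
with one spherical cap covering 15% of the direction sphere replaced by a
plane (smoothly blended at the rim). Radial graphs are star-shaped, so the
mesh is watertight and self-intersection free by construction; both
properties are verified by independent oracles in the tests. The flat cap
gives every seed an unambiguous "ambiguous" region whose interior mean |K|
is orders of magnitude below the bumpy remainder — the contrast that makes
curvature-based ranking non-trivial.

What the fixture does **not** emulate: lobed liver topology and ligament
creases, deformation from pneumoperitoneum or breathing, reconstruction
artefacts other than along-normal Gaussian noise (no outliers, holes, or
spatially correlated error), and occlusion by instruments. Passing
experiments therefore demonstrate that the scoring-registration machinery
behaves as designed on a controllable geometry, not that the specific
clinical effect sizes transfer to patients.

## Experiments and problem sizes

All three experiment drivers share a configuration (`ExperimentConfig`) and
derive every random stream from one master seed via `numpy` seed sequences,
making outputs bit-reproducible. The fixed cloud uses 2000 surface samples;
viewpoints default to 20 random poses on the full sphere; perturbation
trials default to 20 per condition. These sizes were chosen so a full
multi-seed study runs in minutes on a single core while keeping the rank
statistics stable; they are deliberate scale-downs of a study one would run
larger for publication-grade intervals.

The experiments layer defaults to a 30° field-of-view half-angle. A
laparoscope images a limited cone, and the restriction is what makes a
"patch" local: with unlimited FOV, back-face culling on a mostly convex
organ returns near-hemispheric patches, every scenario's convergence basin
saturates the tested rotation range, and patch-count comparisons collapse
into sampling noise. The visibility module itself defaults to pure
back-face culling with no cone, for callers who want the unrestricted
behaviour.

1. **Viewpoint evaluation** scores every viewpoint's patch and runs the
   perturbed registrations, reporting per-viewpoint mean/std TRE (and
   log-mean for visualisation) alongside `f_surface`. The headline
   statistic is the Spearman rank correlation between score and mean TRE,
   expected negative.
2. **Basin of convergence** compares the lowest-scoring patch `P_low`, the
   highest-scoring patch `P_high`, and `P_max` under single-axis rotations
   over ±40° in 24 evenly spaced steps (endpoints inclusive — the phrasing
   "over N steps" is read as N grid angles — plus 0° as a sanity anchor).
   The reported interval per axis is the maximal contiguous run of
   converged angles containing 0°, which mirrors how asymmetric basins are
   naturally reported. Basin trials are rotation-only with noise on.
3. **Patch count** merges k = 1..6 patches selected by strategy (random /
   lowest / highest score), registers each merged cloud under the same 20
   perturbations (shared across strategies, so comparisons are paired), and
   tracks mean TRE against the all-patches `P_max` baseline. Merged clouds
   are voxel-downsampled at 4 mm (the fixed cloud's spacing is ~3 mm, so
   this mainly removes double-counted overlap between patches).

## Numerical choices

- **Curvature**: the quadric fit needs ≥ 6 neighbours; starved points are
  flagged invalid (NaN) and excluded from scores, with a warning above 20%
  invalid. Curvatures follow from the first/second fundamental forms of the
  fitted graph, so the estimate is exact for quadric surfaces and
  rigid-motion invariant to rounding error.
- **ICP**: defaults `max_iterations=200`, `transformation_epsilon=1e-8`, no
  correspondence-distance gate (plain ICP). Degenerate correspondence sets
  (< 3 points) raise.
- **Downsampling**: voxel-grid centroids with averaged, renormalised
  normals; a voxel whose normals cancel exactly keeps its first point's
  normal (measure-zero tie-break).
- **Normal orientation**: outward by majority vote of (vertex − centroid) ·
  normal; well-defined for the closed fixture meshes.
- **Ranking ties**: descending score, then larger patch, then smaller
  viewpoint id — fully deterministic.
- **Units**: millimetres and degrees everywhere in configs and outputs;
  the unit-sphere normalisation helper exists for camera placement and
  round-trips exactly, but TRE and noise are always computed in mm
  coordinates.

## Known limitations

- Back-face culling is exact only for convex shapes; in concavities it
  leaks points a real camera could not see. The HPR option mitigates but
  depends on its radius parameter.
- The signed-vs-absolute scoring ambiguity is inherent to the mean-K
  definition; both variants are first-class and experiments record which
  was used.
- Convergence classification uses a fixed TRE threshold rather than human
  visual inspection; near-threshold trials can flip the contiguous-interval
  width by one grid step between seeds.
- Landmark TRE measures error near one interior cluster; it is not a
  whole-organ error field.
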