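# viewplan

Curvature-driven view planning for rigid CT-to-laparoscope registration,
as a reproducible simulation framework.

## The problem

In image-guided laparoscopic liver surgery, a surface model segmented from the
pre-operative CT scan must be rigidly registered to surface patches
reconstructed from the intra-operative laparoscopic video. Acquiring many
patches is slow and disruptive; acquiring the *wrong* patches (smooth,
featureless regions of the organ) leaves the registration under-constrained
and prone to sliding into wrong poses. `viewplan` simulates the question a
surgical navigation system would like answered before the operation starts:
**from which camera viewpoints should the surface be reconstructed so that a
small number of patches yields an accurate, well-conditioned registration?**

The camera is modelled on a virtual sphere around the organ, constrained by
the trocar port: a central pose (r, θ, φ) in spherical coordinates with
clinician-supplied motion half-ranges (±Δθ, ±Δφ). Each candidate viewpoint is
scored by the mean Gaussian curvature of the surface patch it can see:

    f_surface = (1/N) Σᵢ Kᵢ ,   Kᵢ = k₁ⁱ k₂ⁱ

where k₁, k₂ are the principal curvatures estimated at each visible point
(by default the score averages |Kᵢ|, so saddle-rich and dome-rich patches both
count as distinctive). The hypothesis — checked end to end by the package's
experiments — is that high-scoring (geometrically distinctive) viewpoints
produce lower target registration error (TRE), wider ICP convergence basins,
and need fewer patches than low-scoring (ambiguous, flat) viewpoints.

Registration is plain point-to-point ICP minimising
`min_T Σ ‖P_f − T(P_m)‖²` between the fixed CT cloud `P_f` and a moving
simulated patch `P_m`, with anisotropic reconstruction noise N(0, 1 mm)
applied along the surface normals, and accuracy measured as TRE at interior
landmark points (a simulated abnormality) that never enter the registration.

Because no patient data ships with the package, everything runs on a
synthetic, liver-scale organ fixture: a bumpy ellipsoid with one flattened
region, so distinctive and ambiguous viewpoints both exist by construction.

## Worked example

```python
import numpy as np
import viewplan as vp

mesh = vp.default_fixture(seed=0)                  # liver-scale organ surface
cloud = vp.mesh_to_cloud(mesh, 2000, seed=1)       # P_f, the fixed cloud
landmarks = vp.generate_landmarks(mesh, seed=2)    # simulated abnormality

result = vp.run_viewpoint_evaluation(cloud, landmarks, n_viewpoints=20, seed=0)
best = result.table.sort_values("f_surface", ascending=False).iloc[0]
worst = result.table.sort_values("f_surface", ascending=False).iloc[-1]
print(f"best view  : f_surface={best.f_surface:.5f}  mean TRE={best.mean_tre:.2f} mm")
print(f"worst view : f_surface={worst.f_surface:.5f}  mean TRE={worst.mean_tre:.2f} mm")

from scipy.stats import spearmanr
rho, p = spearmanr(result.table.f_surface, result.table.mean_tre)
print(f"Spearman(score, TRE) = {rho:.2f} (p = {p:.4f})")
```

Output:

```
best view  : f_surface=0.00310  mean TRE=1.38 mm
worst view : f_surface=0.00032  mean TRE=3.67 mm
Spearman(score, TRE) = -0.54 (p = 0.0137)
```

Each of the 20 sampled viewpoints was rendered (30° half-angle cone,
back-face culled), scored, perturbed 20 times (rotations ±10°, translations
±10 mm), and registered back with ICP; the negative rank correlation says
higher-curvature views registered more accurately. `run_basin_experiment`
and `run_patch_count_experiment` run the companion studies (convergence
basins of the best/worst/merged clouds over ±40° single-axis rotations, and
TRE versus number of merged patches per selection strategy).

The same pipelines are available from a shell:

```bash
viewplan fixture --seed 0 --out fixture_out
viewplan eval    --seed 0 --out eval_out
viewplan basin   --seed 0 --out basin_out
viewplan patches --seed 0 --out patches_out
```

Each command writes per-trial and aggregate CSV tables plus a
`run_metadata.json` echoing the master seed for exact replay.

## Documentation

`docs/methods.md` describes the model, the synthetic fixture, parameter
defaults and units, numerical choices, and known limitations.
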