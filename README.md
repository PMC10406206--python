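# ngfreg

Deformable registration of longitudinal (pre- vs post-operative) brain
MRI, built for the situation neuro-oncology imaging actually presents:
intensity profiles that are not comparable across sessions, and
post-operative tissue — the resection cavity and residual pathology —
that has no counterpart in the pre-operative scan.

The package is for researchers who need to map pre-operative anatomy
(tumor outlines, eloquent-area labels, fiber tracts) onto follow-up
scans, and for method developers who want a fully testable variational
registration baseline with exact analytic gradients.

## Method

A non-parametric deformation y(x) = x + u(x) is estimated by minimizing

    J(u) = NGF_{Ω\Σ}(R, T∘y) + α·∫ Σ_k (Δu_k)² dx  [+ γ·∫ ψ(det ∇y) dx]

* **Masked normalized-gradient-fields distance** — per voxel
  ½(1 − ρ²) with ρ = (⟨∇R, ∇T∘y⟩ + ε_R ε_T)/(‖∇T∘y‖_{ε_T}‖∇R‖_{ε_R});
  alignment of intensity-*change directions*, robust to inter-scan
  contrast differences.  Voxels in the pathology mask Σ of the fixed
  image contribute exactly zero, so the missing correspondence cannot
  drag the solution.
* **Curvature regularization** (weight α = 0.1) — penalizes bending,
  leaves affine motion free.
* **Optional volume-change control** (weight γ = 0.01) — barrier
  ψ(t) = (t−1)²/t on the Jacobian determinant; infinite at folding.
* **Multi-level l-BFGS** — 3 levels of 2× restriction from a cubic
  working grid (default 160³), coarse-to-fine with the prolonged field
  warping the moving image and an additive correction estimated per
  level; stopping thresholds 0.001 (progress, gradient, relative
  gradient, step), at most 100 iterations per level.  Deterministic.

Evaluation follows the landmark protocol: fixed-space landmarks are
mapped through y and compared to their pre-operative counterparts
(TRE/mTRE), and paired conditions are tested with the exact Wilcoxon
signed-rank test.  A synthetic phantom generator provides longitudinal
pairs with known ground truth — brain-shift-like deformation, resection
cavity, pathology mask and paired landmarks — so every claim is testable
without external data.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Generate a 64³ phantom pair (4 mm peak brain-shift deformation, 8 mm
resection cavity), register with pathology masking, and evaluate:

```sh
ngfreg phantom --seed 1 --size 64 --out case1
ngfreg register \
    --fixed case1/fixed_T1.nii.gz --moving case1/moving_T1.nii.gz \
    --mask case1/mask.nii.gz --working-size 64 \
    --out-field case1/field.nii.gz
ngfreg evaluate \
    --landmarks-fixed case1/landmarks_fixed.csv \
    --landmarks-moving case1/landmarks_moving.csv \
    --field case1/field.nii.gz --out-report case1/report.csv
```

Output of the last two commands:

```
field written to case1/field.nii.gz; manifest case1/field_manifest.json
  level 2: 100 iterations, objective 20358.4 -> 2593.62 (max_iterations)
  level 1: 100 iterations, objective 13876.4 -> 5194.7 (max_iterations)
  level 0: 100 iterations, objective 13830.5 -> 6526.15 (max_iterations)
baseline mTRE: 1.6211 mm
registered mTRE: 0.4020 mm
```

Reading: before registration the 20 landmarks (healthy tissue near the
cavity) are off by 1.62 mm on average; the estimated deformation reduces
this to 0.40 mm, a 75% error reduction.  The manifest records the
configuration, input hashes, per-level convergence and the folding
fraction of the field (0 — the deformation is injective).  The same
Python API is available via `ngfreg.register`, `ngfreg.compute_tre`,
`ngfreg.generate_phantom_pair`.

`ngfreg compare --a ... --b ...` aggregates per-case reports from two
conditions (e.g. masked vs unmasked) into cohort mTREs with a Wilcoxon
signed-rank p-value, and `ngfreg warp` applies an estimated field to any
other sequence of the same session.

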