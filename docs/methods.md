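# Methods

## Problem setting

`ngfreg` registers a pre-operative (moving, T) onto a post-operative
(fixed, R) brain MRI of the same patient.  Longitudinal neuro-oncology
pairs are hard for standard registration for two reasons: the intensity
profiles of the two scans are not comparable (different sessions,
scanners, sequences), and parts of the post-operative image — the
resection cavity and remaining pathological tissue — have *no anatomical
counterpart* in the pre-operative scan.  The package addresses the first
problem with an edge-based distance and the second by excluding a
segmented pathology mask from the distance integral.

## Model

The deformation is non-parametric, y(x) = x + u(x) with one displacement
vector per voxel, estimated by minimizing

    J(u) = D(R, T∘y) + α·S(u)  [+ γ·V(u)]

### Distance: masked normalized gradient fields (NGF)

Per voxel,

    ρ(x) = (⟨∇R, ∇T∘y⟩ + ε_R ε_T) / (‖∇T∘y‖_{ε_T} ‖∇R‖_{ε_R}),
    d(x) = ½ (1 − ρ(x)²),         ‖v‖_ε = sqrt(vᵀv + ε²),

integrated with the midpoint rule (voxel volume × sum) over Ω \ Σ: voxels
inside the pathology mask Σ contribute exactly zero, as do their
gradients.  NGF scores the *alignment of intensity-change directions*,
which makes it invariant to monotone intensity differences between
sessions — the reason it is preferred over SSD or correlation here.

The edge parameters ε suppress gradients at or below the noise level.
By default they are estimated per image and per pyramid level as
η × mean‖∇v‖ with η = 0.1 (a constant fallback of 1e-3 covers degenerate
constant images); both can be fixed explicitly in the configuration.
Image gradients use spacing-aware central differences, one-sided on
boundary faces.

### Curvature regularization

S(u) = Σ_k ∫ (Δu_k)² penalizes bending; its discrete Laplacian applies
the 7-point stencil only where it fits, with zero second-derivative
contribution on boundary faces (equivalently, linear-extrapolation ghost
values).  This choice makes every *affine* field exactly energy-free —
the discrete counterpart of the harmonicity of affine maps — whereas
mirror-style Neumann ghosts would penalize any nonzero boundary slope.
The operator is therefore not self-adjoint, and the energy gradient uses
the explicit stencil adjoint, 2h·Lᵀ(Lu_k).  The weight default is
α = 0.1.

### Volume-change control (optional)

V(u) = ∫ ψ(det ∇y) with ψ(t) = (t−1)²/t for t > 0 and ψ = ∞ for t ≤ 0 is
a barrier against folding: zero at local volume preservation, infinite at
non-injectivity.  A step that folds any voxel evaluates to the ∞
sentinel and is rejected by the line search rather than crashing the
solve.  The gradient flows through the cofactor (adjugate) matrix of ∇y
and the difference-stencil adjoints.  Default weight γ = 0.01; the term
is **off by default** for the iterative solver, whose reference
formulation lists only NGF + curvature, and can be switched on in the
configuration.

### Exact gradients

The objective gradient is exact for the chosen discretization
(discretize-then-optimize): the warp uses a hand-written trilinear
interpolant whose derivative with respect to the sample coordinate is
computed analytically (zero where samples clamp to the edge), and all
difference stencils are pulled back by their explicit adjoints.  Unit
and acceptance tests verify < 1e-3 maximum relative error against
central finite differences; in practice agreement is ~1e-7.

## Optimization

Limited-memory BFGS (5 stored pairs, two-loop recursion, Armijo
backtracking with factor 0.5 and slope 1e-4; curvature pairs with
sᵀy ≤ 0 are skipped).  The first step is scaled by 1/max(1, ‖g‖) since no
curvature information exists yet.  Termination follows the first
satisfied criterion, all thresholds defaulting to 0.001 with at most
100 iterations per level:

- *minimal progress* — absolute objective decrease per accepted iteration,
- *minimal gradient* — absolute gradient norm,
- *relative gradient* — gradient norm over the initial gradient norm of
  the level,
- *minimal step length* — norm of the accepted update.

The reference description names these criteria and the value 0.001
without defining them; the interpretations above are this package's own.

### Multi-level scheme

Inputs are resampled to a cubic working grid (default edge 160, matching
the clinical pipeline; configurable down to 32 for tests), then restricted
L−1 times by 2×2×2 average pooling (L = 3 by default).  The coarsest
level starts from u = 0 — inputs are assumed rigidly pre-aligned.  After
each level the field is trilinearly prolonged to the next finer grid
(fields are stored in world mm at every level, so no magnitude rescaling
is needed), the moving image is warped with the prolonged guess, and an
*additive correction* is estimated on top of it; the regularizers act on
the accumulated total field.  Whether the reference method composes or
adds the per-level correction is not stated; the additive variant is a
first-order approximation of composition and is the package's choice.
The pathology mask is average-pooled and re-binarized at ≥ 0.5 per level,
approximately preserving pathology volume.  The final field is prolonged
back to the input grid.  The whole solve is deterministic — identical
inputs and configuration give bitwise-identical results.

## Evaluation

Landmarks are ordered, labelled world-mm points, annotated in fixed
space and paired with pre-operative counterparts.  The estimated field
maps a fixed-space point p to p + u(p) (u interpolated trilinearly) —
the direction in which y is defined; the per-landmark target
registration error (TRE) is the Euclidean distance to the paired point,
the per-case mean is the TRE, the cohort mean of case means the mTRE.

Paired conditions are compared with the two-sided Wilcoxon signed-rank
test: zero differences discarded, midranks for ties, exact p-values for
n ≤ 25 via convolution over the doubled ranks (identical to enumerating
all 2ⁿ sign assignments), and a tie-corrected normal approximation with
continuity correction beyond.  The pairing unit is the per-case mean by
default; per-landmark pairing is available behind a flag.

## Synthetic phantom

The generator emulates the data this method targets, with exact ground
truth:

- **Geometry** — a soft-edged anisotropic "head" ellipsoid with a nested
  "ventricle" and unit-variance band-passed noise texture (Gaussian
  scales 1.5 and 4 voxels) standing in for gray/white-matter edges;
  1 mm isotropic cubic grid (default 64³).  Outside the head everything
  is exactly zero, as in skull-stripped data; additive noise
  (σ = 0.02 of the unit intensity scale, an SNR realistic for clinical
  scans) is attenuated by the head support for the same reason.
- **Sequences** — channels are distinct monotone remappings (gamma
  exponents 1.0/0.6/1.6/2.4 for T1/T1-CE/T2/FLAIR flavours) of the shared
  tissue field, optionally scaled per channel; with equal additive noise,
  channel contrast scaling directly sets the edge contrast-to-noise ratio.
  This is intensity simulation only — no MR physics, bias fields or
  k-space artifacts.
- **Ground-truth deformation** — a 50/50 mix of a Gaussian-filtered
  white-noise field (length scale 8 voxels) and a smooth directed
  collapse toward the resection/tumor site (magnitude profile
  (r/s)·exp(½ − r²/2s²), s = 14 mm), emulating post-operative brain
  shift, which concentrates around the resection.  The mix is rescaled
  to the requested peak magnitude (default 4 mm) and damped by 20% steps
  until fold-free.  The moving image is the base anatomy and the fixed
  image is the base *warped by* the truth, so the solver's estimation
  direction matches the construction exactly and no field inversion is
  involved.
- **Pathology** — a spherical cavity blanked to background with a thin
  bright rim exists only in the fixed image; the mask is the cavity
  dilated by one voxel.
- **Landmarks** — sampled at high-gradient healthy voxels, ≥ 2 voxels
  from the border, outside the dilated mask, within a 40 mm band of the
  site (mirroring near-tumor annotation); moving landmarks are the fixed
  ones mapped through the truth field exactly.  The cohort baseline mTRE
  is therefore ~1.5–2 mm at the 4 mm peak — a scaled-down analogue of
  the ~2.9 mm clinical baseline.

What passing phantom tests does *not* show: robustness to bias fields,
inconsistent skull-stripping, pathology-segmentation errors, large-angle
residual rigid misalignment, or anatomy outside the generator's simple
topology.  The phantom's correspondence is exact by construction; real
longitudinal pairs contain biological change beyond the resection.

## Problem sizes and numerical choices

Cohort studies run ten seeded cases at 64³ (recovery and masking) and
48³ (sequence contrast), sizes at which the full 3-level solve finishes
in tens of seconds per pair while leaving the method's behaviour intact;
the clinical-scale default (160³) is the same code path.  Trilinear
sampling clamps out-of-domain coordinates to the edge (skull-stripped
backgrounds are zero, so clamping introduces no artificial edges), with
zero derivative in clamped directions.  The interpolation uses the
two-weight form (w·a + (1−w)·b), which is exact at cell boundaries.
Mask resampling is nearest-neighbour / majority vote only.  Voxel
indices are 0-based; world coordinates are mm at voxel centers;
displacement fields are world-mm 5D NIfTI (nx, ny, nz, 1, 3).

## Known limitations

- The additive per-level correction is not an exact composition; for the
  ≤ 4 mm deformations studied here the discrepancy is well below the
  landmark-error floor.
- The curvature null space includes all affine maps, so a purely affine
  residual is unregularized (by design; inputs are rigidly pre-aligned).
- The exact Wilcoxon branch is O(n·Σ ranks²) and switches to the normal
  approximation above n = 25.
- l-BFGS with the reference stopping rules regularly exhausts the
  100-iteration budget at desk scale; accuracy is then
  optimization-limited, not model-limited (scipy's L-BFGS-B reaches the
  same plateau in cross-checks).
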