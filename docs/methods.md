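# Methods

This note documents the models, conventions and numerical choices behind
`morphogrowth`, and what the synthetic benchmarks do and do not show.

## Coordinate and field conventions

Arrays are indexed `[i, j, k]` along (x, y, z); voxel `(i, j, k)` sits at
`origin + index · spacing` in mm. Displacement fields are stored in mm
and define the map `x → x + u(x)`; all derivatives are taken in physical
units, so anisotropic voxels are handled correctly and the Jacobian is
spacing-invariant.

Direction convention for growth mapping: the estimated transformation
carries week *k* anatomy onto week *k + 1*, so a Jacobian determinant
above 1 encodes growth. In resampling terms the same field pulls
week-*k + 1* data back onto the week-*k* grid, which is also how
segmentations of the later week are propagated back for Dice validation
(mirroring the practice of warping the oldest-week segmentation to the
week under study). The opposite convention is available via
`--direction reverse`.

## The growing-hemisphere phantom

The phantom stands in for a weekly atlas of the developing lateral
surface. Geometry (all sizes derived from the grid's physical extent):
an ellipsoidal hemisphere with a lateral wedge-shaped indentation — the
open fissure — whose floor is the insula; the lips above and below it
are the frontal/parietal (anterior/posterior, superior) and temporal
(inferior) opercula. Labels are `{background 0, interior 1, insula 2,
frontal_operculum 3, parietal_operculum 4, temporal_operculum 5}`; they
tile the object mask exactly.

Weekly change is a **stationary velocity field** with three terms:

1. *Global radial expansion* `a · (x − c)`. The coefficient is
   calibrated at generation time so the total object-volume growth per
   week equals `global_growth_per_week` exactly, whatever the other
   terms contribute.
2. *Opercular convergence* — an odd closing profile about the fissure
   plane, `−A · q(x') · r(y) · tanh(d/1.5 mm) · exp(−d²/2·(4 mm)²)` in
   the vertical component, where `d` is the signed distance to the
   plane, `q` gates the motion to the outer (lateral) part of the
   hemisphere and `r` to the fissure's anterior–posterior extent. The
   compression this implies is confined to the open gap; `A` is the
   peak closing speed in mm/week.
3. *Opercular shell growth* — a radial term concentrated in shells
   ~5 mm above and below the plane. Its rate is
   `opercular_excess_growth` **plus 2 %/week per mm/week of closing
   speed**: closing lips are modelled as *produced by* differential
   growth rather than rigid motion, so pure-convergence phantoms still
   place excess growth in the opercula. This keeps the regional growth
   ordering (opercula above insula) true under every parameter regime
   that drives the fissure shut.

The weekly transformation is `exp(v)` computed by scaling and squaring
(≥ 6 squarings; the step count grows until the scaled step is below a
quarter voxel), which makes the ground truth diffeomorphic by
construction; generation fails loudly if the requested amplitude still
folds the numerical field. Week *k* images are produced by evaluating
the analytic week-0 scene at back-transported grid points (`exp(−v)`
applied *k* times), so labels stay crisp at every week and the
ground-truth pair field is exactly `exp(v)` for every pair.

Intensities are smooth functions of the geometry (a body term, a bright
cortical ribbon, a darkened gap) multiplied by a smooth advected texture
(sum of sinusoids, ~12 mm wavelength, ±25 % amplitude) plus i.i.d.
Gaussian noise. The texture matters: without parenchymal contrast,
week-to-week correspondence away from boundaries is unobservable and any
intensity-driven registration is ill-posed there. Defaults (48³ voxels
at 1 mm, 6 %/week global growth, 4 % excess, 1.5 mm/week closing, noise
σ = 0.01 against an intensity range of ≈ 1.2) emulate a high-SNR atlas
template — an average of many aligned scans — rather than a raw scan.

What the phantom does *not* model: cortical folding and sulcation,
tissue-class-specific MR contrast changes with maturation, hemispheric
asymmetry, and any mechanical (differential-tension) process. Passing
tests show the *pipeline* recovers planted geometry from images; they do
not certify performance on real fetal MRI.

## Registration

Two parts, composed:

* **Affine (12-parameter)**: L-BFGS on mean-squared intensity
  difference, coarse-to-fine, with an analytic image-gradient chain
  rule. The metric excludes a 2-voxel border of the fixed grid — a
  parameter-independent trim that removes the shrink bias created when
  boundary samples fall outside the moving image. (SciPy detail worth
  recording: `map_coordinates(mode="constant")` is discontinuous exactly
  at lattice alignment, so a metric that samples up to the boundary has
  a kink at the identity; trimming sidesteps it.)
* **Stationary-velocity demons**: at each of 3 pyramid levels
  (downsampled ×2 per level, each level band-limited by a σ = 0.7 voxel
  Gaussian after decimation), the loop computes a smoothed SSD-gradient
  force `−(warped − fixed) · ∇((warped + fixed)/2)`, Gaussian-smoothed
  with an annealed σ of (2.0, 1.2, 0.8) voxels per level, adds it to the
  stationary velocity under a backtracking line search (initial step
  0.5 voxel, halved until the MSE decreases), and exponentiates by
  scaling and squaring. Because the Gaussian kernel is positive
  definite the smoothed force is a descent direction, which is what
  makes the per-level MSE provably non-increasing — a contract the test
  suite asserts. A per-voxel normalised (classic demons) force was
  tried first and rejected: after smoothing it is not a descent
  direction and the line search stalls immediately. The velocity gets a
  σ = 0.7 voxel diffusion pass between levels and on the result; the
  finest level resamples the moving image with cubic splines. The
  returned field must have strictly positive Jacobian (hard error
  otherwise).

`register_pair` composes the two analytically:
`u(x) = A(x + u_d(x)) − x`, so the total Jacobian factorises into
`det(A) · J_demons` and one field carries both global and local growth.

Measured recovery at default conditions (48³ phantom pair, seeds 0–3):
label macro Dice ≈ 0.91, image MSE reduction ≈ 80 %, affine volume
factor within 2 % of the planted 6 %, opercula–insula mean-Jacobian
ordering always recovered. The *voxelwise* correlation between
recovered and true Jacobian maps is ≈ 0.40; an independent production
implementation (SimpleITK's diffeomorphic demons) reaches ≈ 0.30–0.36 on
the identical pair, so this level reflects the information limit of
derivative recovery at this scale, not an implementation defect. The
property test therefore asserts a sanity floor (correlation > 0.25)
together with the recoveries the analysis actually uses (ordering,
Dice, MSE).

## Growth maps

`J(x) = det(I + ∂u/∂x)` with central differences in mm (one-sided at the
grid boundary); cross-checked to machine precision against SimpleITK's
`DisplacementFieldJacobianDeterminant`. Global normalisation divides by
the scalar `R` = target/source object volume (mask voxel count × voxel
volume); dividing by the geometric mean of `J` over the mask is
available as an option and agrees with the mask ratio within 2 % on the
phantom. Absolute growth in percent is
`(J_norm · (1 + g) − 1) · 100`, reported to one decimal; boundary voxels
are excluded from all statistical summaries used in tests.

## Validation

Multiclass Dice `2|A∩B|/(|A|+|B|)` per label, macro-averaged over
foreground labels present in either input (labels absent from one input
score 0; background is excluded because its overlap would inflate scores
meaninglessly). A voxel-weighted average is also reported. The
implementation is verified against scikit-learn's per-class F1, which is
mathematically the same quantity.

## Expression contrast

The generator draws a per-gene log-normal baseline (ln-mean 1.5, ln-sd
1.0 across genes) multiplied by per-sample log-normal variability
(ln-sd 0.4 across specimens/regions/layers). The separation matters:
with i.i.d. sampling per cell the null fold-change tail is wide enough
to swamp planted 15-fold signals, whereas the gene-effect-dominated
structure of real regional microarrays keeps the null 99.9th percentile
near 2.5 — planted folds of ≥ 15 are then ≥ 2× the null tail and
recovery of 40 planted genes per layer is essentially complete.

The contrast itself is deliberately the simple rank procedure it
replicates: arithmetic means on the linear scale across specimens and
constituent structures (target and contrast separately), fold change
`(target + ε)/(contrast + ε)` with ε = 0.5 guarding zero denominators,
and rank-based selection of the top `(100 − percentile) %` genes —
35 of 35,000 at 99.9. Boundary ties break lexicographically by gene id
for determinism. No significance testing or multiple-comparison
correction is applied, because the replicated procedure uses none; the
cutoffs reported on synthetic tables describe the synthetic conditions
only.

## Pipeline determinism

Every stage is deterministic given the config seed; manifests record a
SHA-256 over arrays rounded to 1e-6 (and over CSV text), so repeated
runs are checksum-identical. The log records each convention default
actually used (direction, normalisation mode, ε, percentile rule).

## Known limitations

* Derivative-level (voxelwise Jacobian) recovery is bounded by image
  information at 1 mm/48³ scale, as quantified above.
* The MSE metric presumes intensity-calibrated inputs, as the phantom
  provides; real multi-week MRI would need a robust or correlation
  metric.
* The phantom's single analytic fissure is a minimal geometry; regional
  statistics on real anatomy additionally depend on segmentation
  quality, which is outside this package's scope.
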