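# Methods

This note documents the models, conventions and design choices behind
`sabreval`, in the spirit of the methods documentation of mature
scientific packages: what is simulated, how each stage works, which knobs
matter, and what the synthetic results do and do not say about real data.

## Coordinate and grid conventions

All volumes are axis-aligned in a world frame in millimetres; voxel
centers sit at `origin + index * spacing` with 0-based indices.  Oblique
orientations are unsupported by design — the synthetic data is axis-aligned
and the restriction keeps resampling exact and every geometric operation
oracle-checkable.  Dose is carried internally in cGy (the 60 Gy
prescription is 6000 cGy), matching the scale on which the regression
coefficients are expressed.  Outside-grid samples return a role-dependent
fill: −1000 HU (air) for CT-like images, 0 for dose grids and masks.

Displacement fields use the pull-back convention: the field lives on the
fixed (daily/room) grid and a fixed-frame point `x` corresponds to the
moving-frame (planning) point `x + u(x)`.  This makes ACT creation,
structure propagation and dose warp-back single-interpolation operations.

## Synthetic cohort

The phantom cohort is the package's stand-in for a 72-patient clinical
population with four fractions per patient (288 adaptive cases).  Its
defaults are the study conditions:

- **Cohort composition**: 21/15/16/4/16 patients with targets in the
  LUL/LLL/RUL/RML/RLL lobes — four fractions each reproduces the
  84/60/64/16/64 per-lobe case counts of the reference cohort.
- **Anatomy**: a soft-tissue body ellipsoid (+40 HU) on air, two lung
  ellipsoids (−800 HU) with smooth random texture (Gaussian-filtered white
  noise, SD 60 HU) so deformable registration has intensity signal away
  from tissue boundaries; lobe geometry is schematic (five fixed seed
  positions), because only the lobe *label* and the motion-amplitude
  ordering enter the analysis.
- **Targets**: the ITV is an ellipsoid with semi-axes drawn uniformly from
  8–13 mm at the lobe seed position (±2 mm jitter); the PTV is the exact
  Euclidean dilation of the ITV by the configured margin (default 6 mm,
  valid range 5–7 mm).
- **Per-fraction ground truth**: a cubic B-spline displacement field with
  30 mm control-point spacing and i.i.d. normal control coefficients whose
  SD is the per-lobe amplitude; defaults equal the reference cohort's mean
  PTV displacement per lobe (1.57/1.92/1.51/2.47/2.20 mm for
  LUL/LLL/RUL/RML/RLL), which preserves the clinically observed
  lower-lobe > upper-lobe motion ordering.  At these amplitudes the fields
  are far from folding (minimum Jacobian determinant > 0, verified in the
  tests).  A rigid setup error with 1 mm per-axis SD and 5 HU Gaussian
  image noise complete the scenario; the daily image is the planning CT
  warped through setup + deformation.
- **Reference plan**: an analytic dose model — uniform core of the PTV's
  equivalent-sphere radius centred at the isocenter with a Gaussian
  penumbra (σ = 5 mm) — scaled so the planned PTV D95% equals the
  prescription to within 0.1 cGy.  This replaces a treatment planning
  system's dose engine: the analysis layer consumes dose *fields*, not
  transport physics, so HU-dependent heterogeneity effects are out of
  scope by design.

Every generator is a pure function of (config, seed); the global seed is
expanded into per-patient and per-fraction substreams via
`numpy.random.SeedSequence` spawn keys, so any patient or fraction can be
regenerated independently and runs are bit-reproducible.

**Grid profiles.**  Two profiles are provided: `fast` (32³ voxels at
5.0 mm, 160 mm field of view) and `fine` (64³ at 2.5 mm).  The fast
profile is the package's desk-scale default — it runs the full 288-case
cohort, at roughly one deformable registration per second, in a few minutes on
one CPU while preserving every qualitative behaviour of the pipeline; the
fine profile is used where sub-voxel accuracy statements matter (e.g. the
known-truth registration checks).  Clinical-resolution grids (~1.3 mm
in-plane, 512² slices) are out of desk scale and not a package goal.

## Deformable registration

The registration is a documented stand-in for commercial multipass
B-spline algorithms, not a reimplementation of any product; its fidelity is
defined by known-truth recovery on synthetic deformations.

- **Transform**: dense displacement parameterised on a cubic B-spline
  control lattice; multiresolution passes over decreasing control-point
  spacings (library default 40/20/10 mm), each initialised from the
  previous pass's accumulated field.
- **Metric**: mean squared intensity error, normalised by the fixed
  image's intensity variance so the smoothness weight is dimensionless.
  Both images are Gaussian-presmoothed per pass with
  σ = 0.25 × control-point spacing, which lets coarse passes see
  large-scale structure and keeps the quasi-Newton line search stable on
  the piecewise-linear interpolant.
- **Regularisation**: first-difference penalty on control coefficients,
  weight 10⁻³ (normalised per difference).  Chosen on known-truth
  phantoms as the region where endpoint error inside the PTV is minimal
  while the estimated fields remain comfortably invertible.
- **Optimisation**: L-BFGS-B with analytic gradients (the adjoint of the
  separable B-spline expansion), zero initialisation, fixed iteration caps
  — fully deterministic without seeds.  The cohort pipeline uses
  profile-matched presets (fast: 30/15 mm passes, 10 iterations; fine:
  40/20/10 mm, 20 iterations).

Typical fast-profile recovery on default-amplitude scenarios is ~0.2 mm
mean endpoint error inside the PTV; a 6 mm-amplitude field at the fine
profile is recovered to ~0.3 mm (voxel 2.5 mm).

**DVF inversion** uses the fixed-point iteration
`v ← −u(y + v(y))` with adaptive under-relaxation (the step is halved
whenever the update grows), stopping at a 0.01 mm maximum update or 50
iterations; the composition residual `max‖u∘(id+v) + v‖` is attached to
the result and is typically well below 0.01 mm on smooth non-folding
fields.

**QA statistics.**  Warp statistics are min/mean/max displacement
magnitude over the propagated PTV (the PTV is the structure whose
displacement the analysis tracks).  The log-Jacobian summary uses the
natural logarithm of the determinant of `∇(x + u)` (central differences,
one-sided at borders) with linear-interpolation quantiles; the base of the
logarithm and the quantile rule are pinned here because the clinical
convention leaves both unstated.  Voxels with non-positive determinant are
excluded and counted.

## Dose workflow

Per fraction: (1) the recorded setup translation aligns the planning CT;
(2) deformable registration estimates the residual DVF; (3) the total map
(rigid ∘ deformable, composed into a single field) produces the ACT and
the propagated structures (trilinear occupancy thresholded at 0.5);
(4) the per-fraction dose is the analytic plan evaluated in room
coordinates — the dose cloud stays fixed to the plan isocenter, so
anatomical displacement, not the beam, moves — divided by the number of
fractions; (5) the dose is warped back to the planning frame through the
*inverse of the total map*, preserving tissue-element correspondence; and
(6) the four warped-back doses, rescaled to total-course units, are
averaged.  Dose is interpolated as a point quantity with no Jacobian
(mass/energy) weighting, matching the common clinical dose-deformation
convention; this is a known limitation for strongly compressive fields.

Delivered dose statistics per case are computed on the fixed frame over
the propagated structures (as a planning system would report them on the
ACT), while planned-vs-delivered voxel differences are computed in the
planning frame over the original structures.

## Metrics

Dx% is computed by sorted-voxel linear interpolation: the masked doses are
sorted descending and the dose at cumulative volume fraction x/100 is read
off the piecewise-linear curve through the points (i/N, i-th largest
dose).  There is no DVH binning and hence no hidden bin-width parameter;
D100% is the masked minimum and the x→0 limit the maximum.  V100%/V50%
are absolute isodose volumes over the entire dose grid.  Indices follow
the clinical report conventions used throughout:
HI = (D2% − D98%)·100/D_prescribed, ΔHI = HI_delivered − HI_planned,
CI = V100%/structure volume, GI = V100%/V50% (as reported in the clinical
convention this package mirrors — ≤ 1 for nested isodoses, the reciprocal
of the more common definition), and GM = difference of the equivalent-sphere radii of the 50%
and 100% isodose volumes, in mm.  Masks count voxels wholly in or out (no
partial-volume weighting) — a deliberate simplification relative to TPS
small-structure handling, chosen for exact oracles.

A practical consequence of thresholded trilinear propagation worth
knowing: propagated structures are biased very slightly *small* (trilinear
smoothing erodes convex boundaries), so per-fraction volume differences
average marginally below zero even under volume-preserving motion — the
same direction clinical auto-recontouring reports.

## Registration QA metrics

Dice uses the standard 2|A∩B|/(|A|+|B|) with two empty masks defined as
identical.  Surface voxels are the mask minus its 6-connected erosion
(grid-border voxels count as surface); distances are exact Euclidean
via distance transform with anisotropic voxel sampling, pooled over both
directions, and summarised as mean/SD/max.  The pooled symmetric
convention is pinned here because the clinical report format does not
state directionality.

## Statistics layer

The case table (one row per patient-fraction) is analysed as 288
independent observations — within-patient correlation is deliberately not
modelled, matching the standard clinical treatment of fraction-level cases.  The layer provides:

- **OLS** with classical standard errors; standardised
  β_k = B_k·SD(x_k)/SD(y); adjusted R² with the (n−1)/(n−k−1) correction.
- **Stepwise selection**, SPSS-style: repeatedly add the candidate with
  the smallest entry p-value if ≤ p_enter, then remove any included term
  with p ≥ p_remove, to a fixed point.  Defaults 0.05/0.10, the documented
  defaults of the mainstream clinical statistics packages.  Tests that demand a ≥95% exact-selection
  rate against pure-noise candidates run at 0.01/0.05: with two noise
  candidates at entry 0.05 the expected exact-selection rate is only
  ~(1−0.05)² ≈ 90% by construction, so the stricter threshold is a power
  requirement of that check, not a fitted value.
- **Collinearity diagnostics**: VIF_k = 1/(1−R²_k) from regressing each
  term on the others; tolerance = 1/VIF; perfect collinearity reported as
  infinite VIF.
- **One-way ANOVA** by lung lobe (classical F, no Welch correction).
- **Subgroup refit** excluding high homogeneity-index-change cases
  (default ΔHI > 17).  The threshold may alternatively be applied to the
  absolute delivered HI via a flag; ΔHI is the default because the
  distribution the cutoff was drawn from is a ΔHI distribution.
- **Outlier flagging** at |internally studentized residual| > 3 (clinical reports
  often flag outliers without a numeric rule; 3 SD is this package's
  documented choice).

### Tabular generator and calibration

For statistics-layer validation the package generates case tables directly
from the reference fitted model: covariates drawn independently —
ΔHI ~ Gamma(shape 2, scale 2.5); D_mean% ~ Normal(100, 1.63);
DSC ~ Normal(0.97, 0.06) truncated to (0, 1]; Warp_mean ~ Normal(1.82,
1.09) truncated at 0 (the DSC/Warp moments are the reference cohort's
totals; the ΔHI and D_mean% shapes are package defaults, since coefficient
recovery is distribution-agnostic) — and
D95% = intercept + Σ B_k x_k + ε.  The residual SD is calibrated
analytically from the population R²:
σ_ε² = Var(Xβ)·(1−R²)/R² with Var(Xβ) exact under independence (truncated
moments via scipy).  A Gaussian-copula option induces covariate
correlation to exercise VIF > 1; under the copula Var(Xβ) is estimated by
a large fixed-seed Monte-Carlo draw.

## What passing tests do and do not show

The phantoms validate the *machinery*: geometric exactness, known-truth
registration recovery, dose bookkeeping, metric definitions, and
statistical estimator behaviour.  They do not certify clinical accuracy:
real CT texture, CBCT artefacts, respiratory-phase reconstruction,
heterogeneity dose effects, intra-fraction motion and observer contouring
variability are all absent, and the synthetic DSC values run lower than
clinical reports because the structures are small relative to the
fast-profile voxels.  Quantities that depend on those ingredients (e.g.
the clinical regression coefficients from imaging, as opposed to the
tabular generator) are emulated qualitatively, not reproduced.

## Known limitations

- Axis-aligned grids only; no DICOM import/export.
- No organ-at-risk dosimetry, no adaptive re-planning, no intra-fraction
  motion.
- Dose warping ignores Jacobian weighting.
- The B-spline registration has no explicit topology-preservation
  constraint beyond the smoothness penalty (none is needed at the
  configured amplitudes).
- The stepwise procedure inherits the usual caveats of data-driven model
  selection; p-values of selected terms are reported as the clinical
  toolchain reports them, without selection-adjusted inference.
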