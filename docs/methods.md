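# Methods

## The reconstruction problem

A light-sheet microscope built for whole-organ fields of view uses a
thick illumination sheet (axial FWHM ≈ 12 µm) and low-magnification
detection (lateral FWHM ≈ 4.2 µm, 1.625 µm pixels). Both resolution
limits are computational targets here, attacked in two stages:

1. **Sub-voxel-resolving reconstruction (SVR)** per view. The sample is
   scanned *continuously* along a direction S tilted from the detection
   axis z (tilt convention: S = R_y(θ₂)·R_x(θ₁)·ẑ; with a 280 nm step
   and θ₁ = θ₂ = 10°, each frame advances ≈272 nm axially and ≈48 nm
   laterally). Decimating the heavily oversampled frame stream into
   M groups (every M-th frame at a fixed phase) yields M low-resolution
   stacks whose mutual offsets are known sub-voxel fractions of the
   stage geometry. A multi-frame maximum-likelihood estimate fuses them
   on a grid finer by the enhancement factors (rx, ry, rz) = (4, 4, 2).
2. **Multiview deconvolution (MVD)**. The sample is rotated about the
   vertical (y) axis (8 views, 45° apart), each view is reconstructed by
   SVR, the views are registered through point features, and a
   multiview Richardson–Lucy deconvolution with per-view PSFs produces
   one isotropic volume.

## Scan-frame geometry: where the offsets actually live

Stacking frames by index places them in a *sheared* coordinate frame:
plane k is laterally displaced by k·(dx, dy) in sample space. Two
consequences drive the implementation:

- **Inter-group offsets are purely axial in the scan frame.** Group j's
  sampling grid is the scan lattice shifted by j steps *along the scan
  direction*, which is the axial direction of the sheared frame; the
  shear change of variables maps the oblique sample-frame offset j·d to
  (0, 0, j·dz). Equivalently, on the reconstruction grid group j sits at
  exactly j·rz/M axial HR voxels. `GroupingPlan.offsets` keeps the
  sample-frame j·d bookkeeping; the reconstruction consumes
  `GroupingPlan.scan_frame_offsets()`. Phase correlation between groups
  confirms this: measured shifts are axial-only (tested to 0.1 voxel).
- **The PSF must be sheared too.** The optics PSF is axis-aligned in the
  sample frame; in the scan frame its covariance becomes A Σ Aᵀ with A
  the Cartesian→scan shear. The SVR blur kernel is rendered from that
  sheared covariance, so the forward model is exact rather than
  approximated as axis-aligned.

After convergence, `realign` resamples the estimate through the inverse
shear (anchored at the frame-0 plane, recorded in the volume metadata)
back to Cartesian coordinates; round trips preserve smooth volumes at
PSNR > 40 dB.

## The SVR estimator

Each group is modelled as `y_j = D(S_j(H x))`: H is the (sheared)
Gaussian blur, S_j the sub-voxel trilinear shift, and D area-preserving
block-average downsampling by (rz, ry, rx). The Poisson ML estimate is
iterated with the multiplicative multi-frame update

    x ← x · [Σ_j A_jᵀ (y_j / A_j x)] / [Σ_j A_jᵀ 1],

which preserves non-negativity and never increases the data-fit KL
divergence (asserted numerically in the tests). The operator pairs are
exact numerical adjoints — trilinear shift by −o against shift by +o,
replicate/B against block mean, mirrored-kernel against kernel FFT
convolution — verified against dense matrices on 8×8×4 instances to
1e-12; the whole update matches an explicit dense-matrix oracle to 1e-6
per iteration. Because the scan-frame offsets are axial-only, the
lateral part of D commutes with every S_j and is hoisted out of the
per-group loop (identical result, ~(ry·rx)× cheaper).

Choices:

- Initialisation: trilinear interpolation of one LR group onto the HR
  grid with a strictly positive floor (1e-6 × mean).
- Convergence: relative L2 change < 1e-5 or an iteration cap; the
  per-iteration log (KL, relative change) is returned and persisted.
- Offsets: nominal stage geometry by default; a phase-correlation
  estimator (`estimate_offsets`) with quadratic peak interpolation is
  provided and falls back to nominal offsets below a correlation
  confidence threshold.
- An exponentiated update (`corr**q`, q ∈ [1, 2]) is available; q = 1.5
  roughly halves the iterations to a given width and is used by the
  pipeline preset. A least-squares additive update is available behind
  `update="leastsq"`.
- Single precision (`dtype="float32"`) is the pipeline default for
  production-size volumes; the library default stays float64, which the
  oracle-equivalence tests rely on.

## Registration

Beads (or cell bodies, in tissue) are detected as multi-scale
difference-of-Gaussians maxima with per-axis quadratic sub-voxel
refinement. Matching uses rotation/translation-invariant constellation
descriptors (sorted distances to the 4 nearest neighbours, ratio test
0.8) pruned by a seeded random-sample rigid consensus (default inlier
radius 1.5 µm, 1000 draws); the final transform is a closed-form
orthogonal (Kabsch) fit on the inliers, with an affine option for
clearing-induced distortion. The stage pose may seed the consensus —
on an instrument the rotation angle is known — but inlier selection and
the fitted transform come from the data. Known 45° poses are recovered
with < 0.5 voxel RMS landmark error.

## MVD fusion

All views are pulled onto one isotropic reference grid (default voxel =
the lateral HR voxel, 0.40625 µm; the raw-LR fusion path defaults to a
1 µm grid since its resolution target is ≳3 µm). The weighted
simultaneous update is

    ψ ← ψ · [Σ_v (w_v · φ_v / (ψ ⊗ P_v)) ⊗ P_v*] / [Σ_v w_v ⊗ P_v*],

with per-voxel weights w_v ∈ [0, 1] entering the correction term and
its normaliser jointly (a masked voxel neither pulls nor bleaches the
estimate); the weights are applied inside the P_v* correlation in both
numerator and denominator, which is the masked-Poisson-likelihood form
and reduces exactly to classical Richardson–Lucy for one view with unit
weights. Weights combine the resampling validity mask with an
attenuation cutoff: content deeper than −ℓ·ln(threshold) along a view's
illumination axis is discarded with a cosine taper (default 10 µm).
A sequential scheme (one view per sub-step), Biggs–Andrews vector
extrapolation, and the exponentiated update are available; convergence
logs make the schemes comparable.

**Per-view PSFs.** After SVR the view is much sharper than the optics,
so fusing with the optics PSF would misstate the blur. The pipeline
self-calibrates: it measures per-axis bead FWHMs on each SVR volume,
builds a Gaussian PSF from them, and rotates it into the reference
frame with the *fitted* registration transform. The raw-LR fusion path
uses the optics PSF directly.

## Resolution metrology

FWHM is measured by a background-subtracted Gaussian least-squares fit
to a 1D profile through the bead centre (FWHM = 2√(2 ln 2) σ; fits with
R² < 0.8 are rejected). Profiles are sampled on the integer grid along
the profile axis — interpolating along the axis would systematically
broaden the estimate at half-voxel phases — while the sub-voxel centre
offset is absorbed by the fitted mean. Background is the median of the
profile's outer quartiles. Ensemble reports use medians and IQRs over
beads, excluding (but still listing) beads too close to a neighbour or
the volume boundary; the isotropy ratio is median axial over median
lateral FWHM.

## The synthetic-data generator

`synth` renders ground-truth phantoms analytically (beads are Gaussian
blobs with FWHM equal to their nominal diameter, integrated over voxels
with error functions, so flux is exact; filaments are random-walk tubes
with Gaussian cross-sections) and simulates the acquisition chain:
separable Gaussian PSF, mid-step plane sampling of the continuous scan,
camera pixel-area integration, per-view rotation, one-sided exponential
attenuation evaluated at primitive depth, Poisson shot noise and
additive Gaussian read noise (clipped at zero), all seeded. Bead-only
phantoms use an exact analytic frame evaluation; mixed phantoms fall
back to interpolation from a finely rendered blurred volume (the two
paths agree within 5% of peak).

Default study conditions (the pipeline preset): ~0.5 µm beads with
pairwise separation ≥ 12–13 µm in a cylinder inscribed in the field
(so every rotated view sees every bead), bead amplitude set for ≈3000
peak camera counts (shot-noise SNR ≈ 50), read noise 2 counts. The
reduced problem sizes used by the tests (6 beads in a 40 µm field) and
the acceptance script (16 beads in a 52 µm field) keep single-CPU runs
in minutes; resolution figures are field-size independent, so the
scaling affects only the number of beads entering the medians.

What the generator does *not* emulate — and what passing tests
therefore cannot show about real acquisitions: refractive-index
mismatch and depth-dependent PSF aberrations, physical scattering
(only attenuation of excitation), photobleaching, stage jitter or
encoder error (offsets are exact multiples of d), dual-side
illumination, and non-Gaussian PSF side lobes. Real-data resolution
gains will be bounded by these effects; the simulations validate the
estimators, not the instrument.

## Numerical details

- FFT convolutions zero-pad to the full linear-convolution size
  (no circular wrap); the mirrored-kernel OTF implements the exact
  adjoint. MVD pads by the kernel half-width once per run and crops at
  the end; voxels with zero total weight are set to zero.
- ε floors: 1e-6 × mean intensity guard every division and logarithm;
  NaN/Inf aborts with a diagnostic rather than propagating.
- Downsampling is block averaging (area-preserving); decimation would
  alias the sub-voxel information the method depends on.
- Degenerate inputs: all-zero data returns a zero volume with a
  warning; all-zero coverage raises; collinear/coplanar registration
  configurations raise rank errors; flat FWHM profiles raise
  unreliable-fit errors.
- Determinism: every random draw (phantom, noise, RANSAC) flows from an
  explicit seed; the pipeline derives per-stage seeds from one master
  seed via `SeedSequence` and records them in the run manifest.

## Known limitations

- The grouping plan supports G ≤ M groups per axial period; spanning
  multiple periods (e.g. interleaving dual-side illumination stacks) is
  exposed as configuration but not simulated.
- PSFs are Gaussian throughout; the SVR/MVD operators accept any
  rendered kernel, but the self-calibration fits Gaussians only.
- Volumes are processed in memory (desk-scale); no tiling or streaming.
- RL-type deconvolution of point sources keeps sharpening with
  iterations, so reported FWHMs of converged runs depend on the
  iteration budget; convergence logs are persisted so runs can be
  compared at matched budgets.
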