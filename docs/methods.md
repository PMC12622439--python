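# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `psht`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Physical model and conventions

A holotomogram is a 3-D scalar refractive-index (RI) field sampled on a
grid indexed `(z, y, x)` with physical voxel spacing `(dz, dy, dx)` in µm
(default 0.22 × 0.11 × 0.11 µm, taken from the instrument's nominal axial
and lateral resolution; acquisition sampling can differ from optical
resolution, so spacing is always overridable and is carried in OME-TIFF
`PhysicalSize` metadata).  Regions of interest are half-open index ranges
on every axis, 0-based.

Polarization-sensitive holotomography acquires two RI volumes under
orthogonal linear polarizations.  Lipid droplets — an ordered phospholipid
monolayer around a neutral-lipid core — are optically anisotropic: their
apparent RI depends on the probing polarization.  The birefringence map is
the voxelwise absolute difference of the two registered volumes.  The
absolute value guarantees nonnegativity, which every downstream threshold
assumes.  Because other organelles are nearly isotropic, the map is close
to zero outside droplets and a single fixed threshold (0.01, configurable)
segments them across conditions; within a droplet the shell is more
anisotropic than the core, so a line profile through the center is
double-peaked where the single-polarization RI profile is a plateau.

## Registration

The two acquisitions are seconds apart and the sample holder can drift, so
the horizontal (moving) volume is aligned to the vertical (reference)
volume, which is also the polarization used for all RI-based
quantification.

*Lateral stage.*  A 2-D rigid transform (rotation + translation, no
scaling) is estimated between the z-axis maximum-intensity projections
(MIPs), optionally restricted to an ROI around the cell, and applied
identically to every slice with linear interpolation; both volumes are
then cropped to the mutually valid rectangle.  Rotation is found by
exhaustive coarse-to-fine search (±5° at 0.5°, then ±0.5° at 0.05° around
the best candidate); at each candidate rotation the translation is
recovered by subpixel phase correlation, and the candidate is scored by
normalized mutual information (100 bins; mean squares available as an
alternative).  NMI is the default because the two polarizations differ in
intensity exactly where the signal of interest lives (droplets), making a
cross-modality metric appropriate.  Two numerical details matter:

* Both volumes are smoothed with a 3-D Gaussian (σ = 1 voxel) *before*
  projection, for metric evaluation only.  Maximum projection converts
  voxel noise into an extreme-value bias, and on noise-free
  piecewise-constant volumes intensity metrics are biased toward
  near-integer warps, which interpolate less; pre-smoothing removes both
  effects without displacing edges.  The recovered transform is applied to
  the raw volume.
* The search reports non-convergence when the best rotation sits on the
  search boundary.

The recovered transform follows the inverse convention: content displaced
by `+t` yields a recovered correction of `−t`.

*Axial stage.*  Corresponding slice indices can differ between
acquisitions.  Five reference slices are sampled without replacement
(seeded) from the central 80% of the z-range, restricted to slices that
contain structure (smoothed-slice standard deviation at least 0.3 of the
maximum over candidates): a medium-only slice scores every candidate shift
equally well up to noise and would inject a random term into the average.
For each sampled slice, the best-matching moving slice within ±15 slices
is found by maximizing NMI; exact score ties — possible on noise-free
piecewise-constant phantoms — resolve to the smallest displacement.  The
mean shift is rounded to the nearest integer, half away from zero.

Registration is invertible bookkeeping: the recorded transforms
(lateral warp, crop, axial shift) replayed on the raw moving volume
reproduce the aligned volume bit-for-bit, and the reference volume is only
ever cropped, never resampled.

## RI-threshold calibration (Manders sweep)

RI-only droplet segmentation needs a threshold calibrated per condition.
Against a binary fluorescence reference mask (the z-MIP of the droplet
channel at a single global intensity threshold), the RI threshold is swept
over 1.3650…1.3850 in steps of 0.0001 (201 points, configurable).  At each
point the RI MIP is binarized and the Manders coefficients are computed:
M1 is the fraction of reference pixels recovered; M2 the fraction of RI
pixels confirmed.  Thresholding is *inclusive* (`MIP ≥ t`), so a structure
whose RI equals the threshold leaves the mask only once the threshold
passes it.  `dM2/dRI` uses central differences.

`RI_th` is the smallest grid RI at the onset of the M2 plateau, quantified
as: M2 within 5% (relative) of its grid maximum, and |dM2/dRI| below 5% of
its maximum magnitude for the next 10 grid points (both knobs
configurable; an absolute floor of 1e-9 on the derivative tolerance
prevents float jitter from masking an exactly flat curve).  A grid-end
candidate with no lookahead cannot establish a plateau.  If no point
qualifies, the M2 argmax is returned with a flag.  Empty-mask coefficients
propagate as NaN, never 0, so extreme thresholds cannot fake a plateau.
The pipeline's default fluorescence threshold is 20% of the volume's
dynamic range, which captures the full blurred droplet footprint of
wide-field imaging; droplets then appear larger in the reference than in
the RI mask, giving the expected ordering M2 > M1 at `RI_th`.

## Segmentation and quantification

Organelle masks come from disjoint RI intervals on the vertical volume
(defaults: cytosol [1.335, 1.350), nucleus [1.350, 1.365), droplets
[1.375, ∞); all configurable).  The droplet bound is replaced by the
calibrated `RI_th` when a fluorescence reference exists; with neither, the
fixed birefringence rule (> 0.01) stands in.  Mask cleanup removes
26-connected islands smaller than a 0.3 µm-diameter sphere (below the
smallest droplet of interest, 0.5 µm, but above noise specks), then
smooths the float mask with a Gaussian (σ = 1 voxel) and re-binarizes at
0.5 — a symmetric threshold, so large structures keep their volume to
first order.

Volumes are voxel counts times voxel volume.  Dry mass uses the standard
refractive-increment relation of quantitative phase imaging,
`m = (1/α) ∫ (n − n_medium) dV`, with α = 0.185 µm³/pg and
n_medium = 1.337 (PBS), both configurable; voxels below the medium RI are
clipped to zero contribution and reported.  Mass density is mass over
droplet volume (a number density is available via the droplet count, which
uses 26-connectivity).

## Blind Richardson–Lucy deconvolution

The wide-field fluorescence reference is axially blurred (≈1 µm axial
resolution versus ≈0.22 µm lateral).  Blind RL alternates multiplicative
updates of the image estimate and the PSF estimate; nonnegativity is
enforced and the PSF renormalized to unit sum each iteration.  The PSF
initializes as an anisotropic Gaussian from those resolution figures on a
15³ kernel.  Boundary handling is mirror padding (RL ringing depends on
it, so it is fixed and stated); convolution is FFT-based, with an exactly
centred delta kernel short-circuited to the identity so the delta-PSF
fixed point holds exactly rather than to FFT round-off.  Convergence is
monitored by the normalized RMS difference between successive estimates
(NRMSE, normalized by the reference range); iteration stops at `max_iter`
or when the change drops below `tol`.  "Adaptive regularization" is
interpreted as optional total-variation damping with weight λ (default 0,
plain blind RL).

## Cohort statistics and classification

Two-sample comparisons use the two-sided Wilcoxon rank-sum test: exact by
enumeration of all rank assignments when the pooled sample size is at most
12 (ties handled by midranks, i.e. a permutation-exact test on the
observed multiset), otherwise the tie-corrected normal approximation.  The
cutoff balances fidelity and runtime (C(12,6) = 924 assignments).  Raw
p-values are reported; Holm adjustment is available.

Classification emulates separating lipid-loaded from healthy cohorts:
per-cell features (quantification fields and/or birefringence-histogram
bin counts; histograms default to 100 bins on [0, 0.05] plus overflow) are
z-scored, projected onto the top k = 2 principal components, and
classified by a linear discriminant under leave-one-out cross-validation
(nearest centroid as an alternative).  Both PCA and the classifier are
refit in every fold.  The discriminant uses uniform class priors: with
frequency priors, leaving a cell out makes its class the training
minority, so an uninformative discriminant systematically predicts the
opposite class and null-data accuracy collapses toward zero instead of
chance.  Component signs follow the convention that each component's
largest-magnitude loading is positive, making reports stable under
feature reordering.

## The phantom: what it emulates, and what it does not

The generator builds a continuous scene — a cytosol ellipsoid
(RI 1.345) in medium (1.337), a nucleus (1.358, off-center and laterally
anisotropic), optional nucleoli whose RI (default 1.376) overlaps the
droplet range to reproduce the classic confounder of RI-only segmentation,
and spherical droplets with a core–shell Δn structure (defaults: core
0.015, shell 0.035, shell thickness 0.15 µm, chosen to straddle the 0.01
segmentation threshold and the 0.03 high-birefringence histogram level;
droplet diameters default to the physiological 0.5–5 µm range, core RI
sampled per droplet from 1.378–1.390 because a droplet population with one
exact RI value is degenerate under thresholding).  A band-limited random
Fourier texture (std 0.002, wavelengths 0.6–2.4 µm) models intracellular
RI heterogeneity; being an analytic function of position, it moves rigidly
with the specimen and is common to both polarizations, so it cancels in
the birefringence of an aligned pair.  Without texture the phantom's
piecewise-constant slices carry almost no per-slice information and axial
matching becomes artificially ambiguous — a phantom artefact, not a
property of real data.

Two polarization volumes are sampled from this scene: the vertical on the
reference grid; the horizontal with droplet voxels lowered by Δn and — when
misalignment is requested — sampled at rigidly transformed coordinates
(in-plane rotation/translation about the lateral center plus an integer
axial shift).  Sampling the displaced scene analytically, instead of
warping a rasterized volume, mirrors how a physically displaced specimen
is imaged and leaves registration as the only interpolating step.  Noise
is additive Gaussian on RI (default σ = 0.002, a realistic
reconstruction-noise level) and Poisson (200 photons at unit intensity) on
fluorescence, which itself is the droplet mask blurred by an anisotropic
Gaussian (0.2 µm lateral, 1.0 µm axial).

Cohort presets: the lipid-loaded preset (9–13 droplets of 0.8–1.6 µm, all
strongly birefringent) against the healthy preset (6–10 droplets of
0.6–1.2 µm, of which only ~20% carry decrements above 0.01 — droplets with
low lipid ordering) yields roughly 3-fold total droplet volume and roughly
17-fold birefringent volume between classes.  Phantom grids default to
48×96×96 at 0.2×0.1×0.1 µm for cohorts and 64×128×128 for single-cell
studies — sizes chosen so a full cohort analysis runs in seconds on one
core while every structure spans many voxels.

What passing phantom tests does *not* show about real data: the phantom
has no forward optical model (no diffraction, no reconstruction artifacts,
no missing-cone elongation), droplets are perfect spheres with a two-level
Δn rather than a radially varying order parameter, noise is white rather
than structured, and the fluorescence reference has no labeling
heterogeneity or photobleaching.  Results on phantoms validate the
*computational* pipeline — recovery of known transforms, thresholds and
quantities — not instrument performance.

## Reproducibility

Every random operation takes an explicit seed (phantom generation, axial
slice sampling, cohort generation).  The pipeline manifest records a hash
of the canonical config and a checksum per artifact; volume checksums are
computed over the decoded voxel data plus spacing and channel, because
OME-TIFF containers embed a fresh UUID on every write, so identical
content does not give identical file bytes.  Text artifacts are hashed as
bytes.  Identical config and inputs therefore reproduce the manifest
exactly.

## Known limitations

* Lateral registration is exhaustive-search based and assumes isotropic
  lateral spacing and displacements within ±5° / the phase-correlation
  capture range; deformable motion (live cells) is out of scope.
* Under default noise the recovered rotation is accurate to ~0.2°; the
  residual interpolation halo at strong RI discontinuities contributes a
  one-voxel band of spurious birefringence, which the island filter
  removes at the 0.01 threshold but which matters for thresholds near
  zero.
* `RI_th` selection assumes the M2 curve actually plateaus within the
  grid; a confounder whose MIP values interleave with droplet RI values
  forces the plateau (and hence the threshold) above the dimmest droplets,
  which then drop out of the RI mask — the known failure of RI-only
  segmentation that the birefringence channel avoids.
* The Wilcoxon exact path enumerates C(n, n_a) assignments and is gated to
  pooled n ≤ 12 by default.
* Blind RL with a delta initialization stays at the delta fixed point by
  construction; a deliberately broad initialization is required for any
  sharpening.
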