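# Methods

## Phantom model

A phantom is described geometrically (sphere centers, nominal inner
diameters, optional wall shells, a uniform background) and voxelized on
a regular grid. Each voxel value is the activity-weighted mixture of
the materials it intersects,

    value = A·f_sphere + W·f_wall + B·f_background,

with the volume fractions `f` estimated from `oversample³` sub-samples
per voxel (default 4³ = 64). Spheres and walls displace background.
At oversample 4 the total rasterized activity mass agrees with the
analytic geometry to better than 0.5 % for all NEMA sphere sizes; the
discretization error shrinks monotonically as the sub-sampling is
refined.

NEMA diameters are treated as *inner* diameters; the fillable variant
adds an inactive wall shell outside the nominal diameter. The physical
wall thickness of commercial inserts is not standardized in a single
value; the default here is 1 mm, configurable.

Sphere centers sit at a fixed irrational offset
(e/10, π/10, √2/5) mm from the voxel lattice. A center exactly on a
voxel center creates large groups of exactly-degenerate boundary voxel
values (octant symmetry) that no physical acquisition exhibits and that
coarsen threshold sweeps; irrational offsets guarantee that no two
voxels tie in distance to the center, so segmented volumes change in
single-voxel steps near the boundary.

Each sphere is simulated in its own 80 × 80 × 60-voxel sub-volume
(1 × 1 × 2 mm spacing, i.e. 80 × 80 × 120 mm), leaving well over 3·σ of
background margin around the largest sphere. Spheres are analyzed
independently, so nothing is lost relative to a full ring-assembly
simulation and the whole two-variant, six-sphere, five-SBR study runs
in seconds on one core.

## Resolution and noise

Scanner resolution and the reconstruction filter are collapsed into a
single effective isotropic Gaussian PSF applied in image space. The
reconstruction filter alone is typically ~5 mm FWHM; combined with
intrinsic scanner resolution of the same order, the effective default
is 7 mm FWHM (σ = FWHM/2.3548, converted per axis to voxel units, so
anisotropic voxels are handled). Convolution pads the boundary with the
phantom's background value, because the physical object sits in an
extended uniform background. Axes of length 1 (2D fields) are excluded
from the convolution. The implementation satisfies the Gaussian
identities (linearity, mass conservation, half-maximum at a straight
edge, semigroup under composition), which the test suite asserts.

Count-statistics noise is modeled, when requested, as zero-mean
Gaussian voxel noise with standard deviation `relative_sigma · mean`,
added *before* PSF filtering so the filter correlates it spatially the
way reconstruction smoothing does. Absolute count levels of a physical
acquisition are not recoverable from published image-domain data, so
the noise level is a free parameter and the default study is noiseless
(the contrast-independence result is a deterministic property; noise
only adds variance around it). All randomness is driven by explicit
integer seeds; series members derive per-volume seeds from the base
seed, and identical seeds reproduce bit-identical volumes.

## Segmentation and the VRT

Region growing returns the maximal connected component of
`{value ≥ T}` containing the seed voxel; the comparison is inclusive so
that thresholds equal to a voxel value behave deterministically.
Connectivity defaults to 6 (faces) and may be set to 26; for blurred
phantoms the choice does not move the VRT, which a test asserts. The
seed voxel is the intensity-weighted center of mass of a generous
spherical VOI around the sphere.

The absolute volume-reproducing threshold is found by bisection over
`T`, valid because the segmented volume is non-increasing in the
threshold. The search terminates when the volume error falls below half
a voxel or the bracket shrinks below 10⁻⁶ of its initial width; because
the segmented volume only changes at distinct voxel values, the few
values remaining inside a converged bracket are then enumerated
exactly, so a volume step hiding between two near-identical values
cannot be skipped. Ties (threshold plateaus on discrete images) resolve
to the smallest visited threshold. Default search bounds are (image
minimum, seed intensity); if the target volume is not bracketed the
error names the failing bound.

## Reference activity and the relative VRT

The relative VRT is (T − B)/(A − B). B is the true background
concentration in simulations (for external images, the mean of a
user-supplied background VOI). For A, two conventions exist: the true
filled concentration, or the image-mean activity over the sphere's true
geometry. Only the image-mean convention makes the VRT *decrease* with
sphere size (small spheres lose more of their mean to partial-volume
spill-out, which inflates the VRT relative to that depressed mean) and
places the large-sphere VRT near 50 %, the behaviors expected of
mean-normalized thresholds; it is therefore the default, with
`reference: "true"` available as a config switch for sensitivity
analyses. Under either convention the wall-less VRT is exactly
contrast-independent in noiseless simulations, because the image is an
affine function of the blurred sphere indicator.

With the defaults (7 mm FWHM, 1 × 1 × 2 mm voxels) the simulated
wall-less VRTs run from 70 % (10 mm) down to 54 % (37 mm), decreasing
monotonically with diameter; the walled variant falls below the
wall-less VRT at every contrast, with the deficit growing as the SBR
drops, and cross-applying walled-derived thresholds to wall-less
images overestimates volumes most for the smallest sphere at the
lowest contrast. These orderings — not exact magnitudes, which depend
on the unknown wall thickness and effective resolution of any given
scanner — are the validated claims.

## Uniformity statistics

The CV of voxel intensities is computed in a 27 mm central VOI (inside
the 37 mm sphere, excluding spill-in/spill-out). Distributions between
sphere types are compared with a histogram Kullback–Leibler divergence
(64 shared equal-width bins spanning the union range, 10⁻¹²
regularization per bin, natural log, first argument = test
distribution) and the two-sample Kolmogorov–Smirnov statistic with the
asymptotic p-value at effective sample size n_a·n_b/(n_a+n_b) — voxel
counts are in the thousands, so the asymptotic form is appropriate.
Voxels are treated as i.i.d. samples; PSF-induced spatial correlation
is acknowledged, not modeled, so the KS p-values are anti-conservative
in absolute terms and are used comparatively.

The autoradiography generator emulates a thin printed slab read out at
25 µm: a uniform baseline plus Poisson-placed Gaussian hotspots
(microscopic regions of elevated counts) plus independent pixel noise.
Defaults (0.09 hotspots/mm², amplitude 0.5 × baseline, 1 mm FWHM,
5 % pixel noise) were set from Campbell's theorem for shot noise to
give a raw CV near 12 %, which 5 mm FWHM Gaussian filtering — the
reconstruction-scale filter — reduces to about 2 %. The exact smoothed
value depends on the hotspot correlation length, which is not
measurable from published figures; the robust property is that
smoothing strictly reduces the CV of any non-constant field.

## CT attenuation conversion

CT Hounsfield units convert to 511 keV linear attenuation via the
bilinear transform μ = 9.6·10⁻⁵·(HU + 1000) cm⁻¹ below the breakpoint
and μ = 5.1·10⁻⁵·(HU + 1000) + 4.71·10⁻² cm⁻¹ above it. The breakpoint
is derived from the constants (≈ 46.7 HU, commonly quoted as 47 HU) so
the transform is exactly continuous; with rounded published constants a
hard-coded 47 HU breakpoint would leave a 1.5·10⁻⁵ cm⁻¹ step. All
constants are arguments, so published variants of the transform can be
substituted.

## What the synthetic data does and does not show

The generator reproduces the *geometric and resolution* structure of a
sphere-phantom session: partial-volume blurring, cold-wall
displacement, contrast titration, discretization. It does not simulate
projection-domain physics (attenuation, scatter, randoms, OSEM
convergence, reconstruction artifacts), acquisition-time matching of
counts across SBRs, or material effects (leaching, density). Passing
tests therefore validate the analysis pipeline and the structural
claims about thresholds and walls under an idealized imaging model —
not scanner-specific magnitudes, which require the physical experiment.

## Problem sizes

The standard study is 2 variants × 6 spheres × 5 SBRs = 60 simulated
sub-volumes of 384 000 voxels each, with ~20–40 region-growing
evaluations per bisection; it completes in well under a minute on one
core. The test suite additionally runs a 104 × 104 × 52 volume for the
80 mm large-sphere limit and Monte-Carlo noise replicates for the CV
oracle.
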