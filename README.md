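# petvrt

Digital PET sphere phantoms and volume-reproducing-threshold (VRT)
analysis for wall-less vs. fillable phantom studies.

## The problem

Threshold-based target delineation in PET is usually validated with
fillable NEMA-style sphere phantoms. The plastic wall of a fillable
sphere contains no activity, and this *cold wall* depresses intensities
near the object boundary, making the optimal segmentation threshold
depend on the image contrast — exactly the regime (low
signal-to-background ratio, SBR) where clinical segmentation matters
most. Wall-less phantoms (radioactive solid spheres sitting directly in
an active background) remove that bias, and their optimal threshold is
contrast-independent.

`petvrt` reproduces this comparison entirely in software, for people
who develop or validate PET segmentation methods: it synthesizes
voxelized, PSF-blurred sphere phantoms in both variants, determines
volume-reproducing thresholds by seeded region growing, and quantifies
the contrast (in)dependence of the threshold, the volume errors caused
by cold walls, and activity-distribution uniformity.

## The model

- A phantom is a set of spheres of diameter *D* (NEMA sizes
  10/13/17/22/28/37 mm) with activity concentration *A* in a background
  of concentration *B* = *A*/SBR, optionally separated from it by an
  inactive wall shell. Spheres are voxelized on a 1 × 1 × 2 mm grid
  with sub-voxel antialiasing.
- Scanner resolution and reconstruction filtering are modeled as one
  effective isotropic Gaussian point-spread function (default FWHM
  7 mm).
- Segmentation is region growing: the connected set of voxels ≥ *T*
  containing a seed voxel. The absolute volume-reproducing threshold
  *T* is found by bisection so the segmented volume matches the known
  true volume *V* = (π/6)·*D*³.
- The background-corrected relative threshold

  VRT = (T − B) / (A − B)

  with *A* the image-mean activity over the sphere's true geometry, is
  the contrast-independent summary quantity. Its coefficient of
  variation across SBRs measures contrast dependence; applying a
  walled-derived VRT to wall-less images measures the resulting volume
  overestimation 100·(V* − V)/V.
- Uniformity of the activity distribution is quantified by the CV of
  voxel intensities in a central VOI and compared between sphere types
  with the Kullback–Leibler divergence and the two-sample
  Kolmogorov–Smirnov statistic; a synthetic 25 µm autoradiography-like
  field with microscopic hotspots shows how reconstruction-scale
  Gaussian filtering suppresses microscopic non-uniformity.

## Worked example

```python
from petvrt import (PsfSpec, single_sphere_phantom, simulate_sbr_series,
                    spherical_voi, center_of_mass, find_vrt_threshold,
                    reference_activity, relative_vrt)

phantom = single_sphere_phantom(37.0, sphere_activity=10.0)
for sbr, (img, spec) in zip([2, 10], simulate_sbr_series(phantom, [2, 10], PsfSpec(7.0))):
    sphere = spec.spheres[0]
    seed = center_of_mass(img, spherical_voi(sphere.center, 47.0, img))
    seg = find_vrt_threshold(img, seed, sphere.true_volume)
    vrt = relative_vrt(seg.threshold, reference_activity(img, sphere), spec.background_activity)
    print(f"SBR {sbr:2d}: T = {seg.threshold:.3f}, V = {seg.volume:.0f} mm^3, VRT = {100*vrt:.1f} %")
```

prints

```
SBR  2: T = 7.179, V = 26522 mm^3, VRT = 54.0 %
SBR 10: T = 4.922, V = 26522 mm^3, VRT = 54.0 %
```

The absolute threshold moves with the background (7.18 at SBR 2 vs 4.92
at SBR 10), but the background-corrected VRT of the wall-less 37 mm
sphere is 54.0 % at both contrasts — the contrast independence that
makes wall-less phantoms attractive — and the segmented volume matches
the true 26 522 mm³ to better than one voxel.

The full study (both variants, six sphere sizes, five SBRs) runs from
the command line:

```sh
petvrt run-all --out results/
```

which reports, among others, a mean VRT CV over SBRs of 0.00 % for the
wall-less spheres vs. 9.60 % for the walled ones, and writes the VRT,
difference and overestimation tables (CSV), plots, and a run log. See
`petvrt --help` for the individual subcommands (`simulate`,
`vrt-curve`, `overestimate`, `uniformity`, `autoradiography`, `hu2mu`).

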