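"""Background-corrected relative VRT and contrast-dependence analysis.

The absolute threshold T that reproduces an object's volume depends on
the activities in play; the background-corrected *relative* VRT

    VRT = (T - B) / (A - B)

removes that dependence (A = reference activity concentration of the
object, B = background concentration).  For an ideal wall-less object
imaged with a shift-invariant PSF the relative VRT is exactly
independent of the signal-to-background ratio (SBR); an inactive wall
between object and background breaks that independence at low contrast.

By default A is the image-mean activity over the sphere's true geometry
(so the VRT decreases with sphere size, as partial-volume losses shrink
the mean of small spheres more); the true filled concentration can be
used instead for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import ImageVolume, VoiMask
from .phantom_sim import SphereSpec
from .segmentation import center_of_mass, connected_threshold, spherical_voi

__all__ = [
    "VrtRecord",
    "OverestimationRecord",
    "ProfileSeries",
    "relative_vrt",
    "measure_sbr",
    "reference_activity",
    "vrt_contrast_cv",
    "cross_apply_vrt",
    "radial_intensity_profile",
]


@dataclass(frozen=True)
class VrtRecord:
    """One sphere at one SBR: absolute threshold T and relative VRT."""

    sphere_id: str
    sphere_diameter: float
    sbr: float
    threshold: float
    reference_activity: float
    background_activity: float
    vrt: float

    @classmethod
    def from_threshold(
        cls,
        sphere_id: str,
        sphere_diameter: float,
        sbr: float,
        threshold: float,
        reference_activity: float,
        background_activity: float,
    ) -> "VrtRecord":
        return cls(
            sphere_id=sphere_id,
            sphere_diameter=float(sphere_diameter),
            sbr=float(sbr),
            threshold=float(threshold),
            reference_activity=float(reference_activity),
            background_activity=float(background_activity),
            vrt=relative_vrt(threshold, reference_activity, background_activity),
        )


@dataclass(frozen=True)
class OverestimationRecord:
    """Volume error from applying a foreign (walled-derived) VRT."""

    sphere_id: str
    sbr: float
    true_volume: float
    segmented_volume: float

    @property
    def overestimation_percent(self) -> float:
        return 100.0 * (self.segmented_volume - self.true_volume) / self.true_volume


@dataclass(frozen=True)
class ProfileSeries:
    """Mirrored radial intensity profile of one sphere.

    ``points`` is an (n, 2) array of (signed radial distance mm,
    intensity), symmetric under r -> -r by construction.
    ``reference_level`` carries the true activity concentration and
    ``vrt_level`` the absolute threshold, for plotting.
    """

    points: np.ndarray
    reference_level: float
    vrt_level: float | None = None


def relative_vrt(threshold: float, a: float, b: float) -> float:
    """Background-corrected relative VRT, (T - B) / (A - B)."""
    if a <= b:
        raise ValueError(f"reference activity A={a:g} must exceed background B={b:g} (undefined contrast)")
    return (threshold - b) / (a - b)


def measure_sbr(
    img: ImageVolume,
    largest_sphere_center,
    background_voi: VoiMask,
    voi_diameter: float = 20.0,
) -> float:
    """Image-derived SBR: 20 mm central-VOI mean over background-VOI mean.

    The central VOI sits in the middle of the largest sphere, where PSF
    spill from the background is negligible.
    """
    center_voi = spherical_voi(largest_sphere_center, voi_diameter, img)
    if center_voi.count == 0:
        raise ValueError("central VOI contains no voxels")
    bg = background_voi.extract(img)
    bg_mean = float(bg.mean()) if bg.size else 0.0
    if bg_mean <= 0:
        raise ValueError("background VOI mean must be > 0")
    return float(center_voi.extract(img).mean()) / bg_mean


def reference_activity(img: ImageVolume, sphere: SphereSpec) -> float:
    """Mean image intensity over the sphere's true geometry.

    This is the mean-based reference A used in the relative VRT: the
    average of the (blurred) image over the sphere's nominal spherical
    volume.  It is below the filled concentration for any blurred image.
    """
    voi = spherical_voi(sphere.center, sphere.inner_diameter, img)
    if voi.count == 0:
        raise ValueError(f"sphere {sphere.id!r} true-geometry VOI contains no voxels")
    return float(voi.extract(img).mean())


def vrt_contrast_cv(records: list[VrtRecord]) -> tuple[pd.Series, float]:
    """Per-sphere CV of the VRT across SBRs, and its unweighted mean.

    CV = sample standard deviation (n-1) over mean of the relative VRT
    across the SBR series, computed per sphere and then averaged over
    spheres with equal weight.
    """
    if not records:
        raise ValueError("no VRT records")
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.sphere_id, []).append(r.vrt)
    cvs = {}
    for sphere_id, vrts in groups.items():
        if len(vrts) < 2:
            raise ValueError(f"sphere {sphere_id!r} has only one record; CV over SBRs needs >= 2")
        arr = np.asarray(vrts)
        cvs[sphere_id] = float(arr.std(ddof=1) / arr.mean())
    series = pd.Series(cvs, name="vrt_cv")
    return series, float(series.mean())


def cross_apply_vrt(
    vrt_from_walled: float,
    a: float,
    b: float,
    wallless_img: ImageVolume,
    seed_voxel,
    true_volume: float,
    sphere_id: str = "",
    sbr: float = float("nan"),
    connectivity: int = 6,
) -> OverestimationRecord:
    """Segment a wall-less image with a VRT derived from a walled phantom.

    The relative VRT is converted back to an absolute threshold
    ``T = B + VRT * (A - B)`` using the wall-less image's own A and B,
    and fed to the region-growing segmentation.  Because the
    walled-derived VRT is biased low (cold-wall effect), the resulting
    volume overestimates the truth, most severely at low SBR.
    """
    if a <= b:
        raise ValueError("reference activity must exceed background")
    threshold = b + vrt_from_walled * (a - b)
    seg = connected_threshold(wallless_img, seed_voxel, threshold, connectivity)
    return OverestimationRecord(
        sphere_id=sphere_id,
        sbr=float(sbr),
        true_volume=float(true_volume),
        segmented_volume=seg.volume,
    )


def radial_intensity_profile(
    img: ImageVolume,
    sphere: SphereSpec,
    margin: float = 10.0,
    vrt_level: float | None = None,
) -> ProfileSeries:
    """All voxel intensities against radial distance from the center of mass.

    Voxels within ``inner_radius + margin`` of the sphere's
    center-of-mass voxel are emitted as (distance, intensity) points and
    mirrored to negative distances (r = 0 is not duplicated), giving the
    familiar symmetric sphere-profile plot.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    search_voi = spherical_voi(sphere.center, sphere.inner_diameter + 2.0 * margin, img)
    if search_voi.count == 0:
        raise ValueError("profile VOI contains no voxels")
    com_idx = center_of_mass(img, search_voi)
    com_pos = img.index_to_world(com_idx)

    dist = img.radial_distances(com_pos)
    sel = dist <= sphere.inner_radius + margin
    if not sel.any():
        raise ValueError("profile VOI contains no voxels")
    r = dist[sel]
    v = img.values[sel]
    mirror = r > 0
    points = np.concatenate(
        [np.column_stack([r, v]), np.column_stack([-r[mirror], v[mirror]])]
    )
    points = points[np.argsort(points[:, 0], kind="stable")]
    return ProfileSeries(points=points, reference_level=sphere.sphere_activity, vrt_level=vrt_level)
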