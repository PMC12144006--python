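"""Seeded region-growing segmentation and the volume-reproducing threshold.

The volume-reproducing threshold (VRT) of an object with known true
volume is the absolute intensity threshold at which the thresholded
connected region containing the seed has exactly the true volume.  It is
found by bisection, exploiting that the segmented volume is
non-increasing in the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImageVolume, VoiMask

__all__ = [
    "SegmentationResult",
    "SeedBelowThresholdError",
    "connected_threshold",
    "find_vrt_threshold",
    "center_of_mass",
    "spherical_voi",
]

logger = logging.getLogger(__name__)


class SeedBelowThresholdError(ValueError):
    """The seed voxel's intensity is below the requested threshold."""


@dataclass(frozen=True)
class SegmentationResult:
    """A connected-threshold segment: mask, absolute threshold and volume."""

    mask: VoiMask
    threshold: float
    volume: float
    seed_voxel: tuple[int, int, int]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def connected_threshold(
    img: ImageVolume,
    seed_voxel,
    threshold: float,
    connectivity: int = 6,
) -> SegmentationResult:
    """Region growing: the connected set of voxels >= threshold containing the seed.

    The comparison is inclusive (``value >= threshold``), so a threshold
    equal to a voxel value includes that voxel.  Default connectivity is
    6 (faces); 26 includes edges and corners.

    Raises
    ------
    IndexError
        If the seed voxel lies outside the grid.
    SeedBelowThresholdError
        If the seed voxel's intensity is below the threshold.
    """
    seed = tuple(int(i) for i in seed_voxel)
    if not img.contains_index(seed):
        raise IndexError(f"seed voxel {seed} outside grid of shape {img.shape}")
    if img.values[seed] < threshold:
        raise SeedBelowThresholdError(
            f"seed voxel {seed} has value {img.values[seed]:g} < threshold {threshold:g}"
        )
    above = img.values >= threshold
    labels, _ = ndimage.label(above, structure=_structure(connectivity))
    mask = labels == labels[seed]
    voi = VoiMask(mask, img.voxel_spacing)
    return SegmentationResult(mask=voi, threshold=float(threshold), volume=voi.volume, seed_voxel=seed)


def find_vrt_threshold(
    img: ImageVolume,
    seed_voxel,
    true_volume: float,
    search_bounds: tuple[float, float] | None = None,
    connectivity: int = 6,
    bracket_rtol: float = 1e-6,
) -> SegmentationResult:
    """Absolute volume-reproducing threshold by bisection.

    Searches for the threshold T at which the connected segment through
    the seed has volume ``true_volume``.  Because the segmented volume
    is non-increasing in T, bisection applies; it terminates when the
    best volume error drops below half a voxel or the bracket width
    falls below ``bracket_rtol`` times the initial bracket.  The result
    is the best-visited iterate; among ties the smallest T is returned
    (discrete images have threshold plateaus).

    ``search_bounds`` defaults to ``(min(img), img[seed])`` — i.e. from a
    background-level threshold segmenting (essentially) everything down
    to the seed intensity segmenting (essentially) nothing beyond the
    seed's level set.  The bracket must satisfy
    ``V(lower) >= true_volume >= V(upper)``.
    """
    if true_volume <= 0:
        raise ValueError("true_volume must be > 0")
    seed = tuple(int(i) for i in seed_voxel)
    if not img.contains_index(seed):
        raise IndexError(f"seed voxel {seed} outside grid of shape {img.shape}")

    if search_bounds is None:
        lo, hi = float(img.values.min()), float(img.values[seed])
    else:
        lo, hi = (float(b) for b in search_bounds)
    if not lo < hi:
        raise ValueError(f"invalid search bounds ({lo:g}, {hi:g})")

    cache: dict[float, SegmentationResult | None] = {}

    def segment(t: float) -> SegmentationResult | None:
        if t not in cache:
            try:
                cache[t] = connected_threshold(img, seed, t, connectivity)
            except SeedBelowThresholdError:
                cache[t] = None
        return cache[t]

    def volume(t: float) -> float:
        seg = segment(t)
        return seg.volume if seg is not None else 0.0

    v_lo = volume(lo)
    v_hi = volume(hi)
    if v_lo < true_volume:
        raise ValueError(
            f"lower bound {lo:g} fails the bracket: segmented volume {v_lo:g} mm^3 "
            f"< target {true_volume:g} mm^3 (target unreachable within bounds)"
        )
    if v_hi > true_volume:
        raise ValueError(
            f"upper bound {hi:g} fails the bracket: segmented volume {v_hi:g} mm^3 "
            f"> target {true_volume:g} mm^3 (target unreachable within bounds)"
        )

    half_voxel = img.voxel_volume / 2.0
    width0 = hi - lo

    best_t, best_err = hi, abs(v_hi - true_volume)
    if abs(v_lo - true_volume) < best_err or (abs(v_lo - true_volume) == best_err and lo < best_t):
        best_t, best_err = lo, abs(v_lo - true_volume)

    while best_err >= half_voxel and (hi - lo) > bracket_rtol * width0:
        mid = 0.5 * (lo + hi)
        v = volume(mid)
        err = abs(v - true_volume)
        if err < best_err or (err == best_err and mid < best_t):
            best_t, best_err = mid, err
        if v > true_volume:
            lo = mid
        else:
            hi = mid

    if best_err >= half_voxel:
        # the mask only changes at voxel values; enumerate the few distinct
        # values left inside the converged bracket so a volume step hiding
        # between two near-identical values is not skipped
        in_bracket = np.unique(img.values[(img.values > lo) & (img.values <= hi)])
        for t in in_bracket:
            v = volume(float(t))
            err = abs(v - true_volume)
            if err < best_err or (err == best_err and t < best_t):
                best_t, best_err = float(t), err

    result = segment(best_t)
    if result is None:  # pragma: no cover - best iterate always segmentable
        raise RuntimeError("internal error: best threshold excludes the seed")
    return result


def center_of_mass(img: ImageVolume, voi: VoiMask) -> tuple[int, int, int]:
    """Intensity-weighted mean position over a VOI, rounded to a voxel index."""
    weights = voi.extract(img)
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("VOI has non-positive total intensity; center of mass undefined")
    coords = np.argwhere(voi.mask)
    com = (coords * weights[:, None]).sum(axis=0) / total
    return tuple(int(i) for i in np.round(com))


def spherical_voi(center, diameter: float, img: ImageVolume) -> VoiMask:
    """Voxels whose centers lie within ``diameter/2`` of a physical point (mm)."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    mask = img.radial_distances(center) <= diameter / 2.0
    if not mask.any():
        logger.warning("spherical VOI (center %s, diameter %g mm) contains no voxels", tuple(center), diameter)
    return VoiMask(mask, img.voxel_spacing)
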