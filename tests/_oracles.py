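"""Independent oracles used by the tests.

These are deliberately naive implementations (breadth-first flood fill,
exhaustive ECDF evaluation, closed-form blurred-sphere profile) kept
separate from the library code they check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy import integrate

from petvrt.image import ImageVolume
from petvrt.phantom_sim import FWHM_TO_SIGMA

OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill(values: np.ndarray, seed: tuple[int, int, int], threshold: float, connectivity: int = 6) -> np.ndarray:
    """Brute-force BFS flood fill of the >= threshold region containing seed."""
    offsets = OFFSETS_6 if connectivity == 6 else OFFSETS_26
    shape = values.shape
    mask = np.zeros(shape, dtype=bool)
    if values[seed] < threshold:
        raise ValueError("seed below threshold")
    mask[seed] = True
    queue = deque([seed])
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                if not mask[nx, ny, nz] and values[nx, ny, nz] >= threshold:
                    mask[nx, ny, nz] = True
                    queue.append((nx, ny, nz))
    return mask


def ecdf_ks_statistic(sample_a, sample_b) -> float:
    """Exhaustive sup |ECDF_a - ECDF_b| over all sample points."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    points = np.concatenate([a, b])
    best = 0.0
    for x in points:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return float(best)


def blurred_sphere_profile(r, radius: float, sigma: float):
    """Closed-form radial profile of a unit uniform sphere blurred by a Gaussian.

    Convolution of the indicator of a sphere of the given radius with an
    isotropic 3D Gaussian of standard deviation sigma, as a function of
    distance r from the sphere center.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r).copy()
    out = np.empty_like(r)
    s2 = sigma * math.sqrt(2.0)
    small = r < 1e-9 * max(radius, sigma)
    # r -> 0 limit
    out[small] = math.erf(radius / s2) - (radius / sigma) * math.sqrt(2.0 / math.pi) * math.exp(
        -(radius**2) / (2 * sigma**2)
    )
    rr = r[~small]
    term1 = 0.5 * (np.vectorize(math.erf)((radius - rr) / s2) + np.vectorize(math.erf)((radius + rr) / s2))
    term2 = (sigma / (rr * math.sqrt(2.0 * math.pi))) * (
        np.exp(-((rr - radius) ** 2) / (2 * sigma**2)) - np.exp(-((rr + radius) ** 2) / (2 * sigma**2))
    )
    out[~small] = term1 - term2
    return float(out[0]) if scalar else out


def blurred_sphere_mean(radius: float, sigma: float, voi_radius: float | None = None) -> float:
    """Volume-average of the blurred unit sphere over a concentric spherical VOI."""
    voi_radius = radius if voi_radius is None else voi_radius
    integrand = lambda r: blurred_sphere_profile(r, radius, sigma) * r**2
    val, _ = integrate.quad(integrand, 0.0, voi_radius, limit=200)
    return 3.0 * val / voi_radius**3


def analytic_blurred_sphere_image(
    diameter: float,
    fwhm: float,
    sphere_activity: float = 10.0,
    background_activity: float = 1.0,
    grid_shape=(80, 80, 60),
    spacing=(1.0, 1.0, 2.0),
    center_offset=None,
):
    """Image built directly from the closed-form blurred-sphere profile.

    Returns (image, center_mm).  No rasterization or discrete convolution
    is involved, so this is an independent stand-in for the simulated
    phantoms.
    """
    from petvrt.phantom_sim import DEFAULT_CENTER_OFFSET

    if center_offset is None:
        center_offset = DEFAULT_CENTER_OFFSET
    shape = np.asarray(grid_shape)
    sp = np.asarray(spacing, dtype=float)
    center = (shape - 1) / 2.0 * sp + np.asarray(center_offset)
    sigma = fwhm * FWHM_TO_SIGMA
    axes = [np.arange(shape[a]) * sp[a] - center[a] for a in range(3)]
    r = np.sqrt(
        axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    )
    profile = blurred_sphere_profile(r.ravel(), diameter / 2.0, sigma).reshape(r.shape)
    values = background_activity + (sphere_activity - background_activity) * profile
    return ImageVolume(values, tuple(sp), (0.0, 0.0, 0.0)), tuple(center)
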