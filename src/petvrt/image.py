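"""Core image containers.

An :class:`ImageVolume` is a 3D intensity grid with a physical voxel
spacing and origin, the common carrier for all image-domain data in this
package.  2D fields (e.g. autoradiography images) use a singleton third
axis.  A voxel's physical position is the position of its *center*; the
voxel with index ``(0, 0, 0)`` is centered at ``origin``.  All geometry
is in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "VoiMask"]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D intensity grid with physical voxel spacing and origin (mm)."""

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"values must be a 3D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image values must all be finite")
        spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be three positive numbers, got {self.voxel_spacing}")
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise ValueError("origin must be a 3-vector")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers along each axis (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def index_to_world(self, index) -> np.ndarray:
        """Physical position (mm) of the center of voxel ``index``."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.voxel_spacing)

    def world_to_index(self, point) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to ``point`` (mm)."""
        rel = (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.voxel_spacing)
        return tuple(int(i) for i in np.round(rel))

    def contains_index(self, index) -> bool:
        return all(0 <= int(i) < n for i, n in zip(index, self.shape))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """A new volume sharing this volume's geometry."""
        return ImageVolume(values, self.voxel_spacing, self.origin)

    def radial_distances(self, center) -> np.ndarray:
        """Distance (mm) from every voxel center to a physical point."""
        xs, ys, zs = self.axis_coordinates()
        cx, cy, cz = (float(c) for c in center)
        d2 = (
            (xs - cx)[:, None, None] ** 2
            + (ys - cy)[None, :, None] ** 2
            + (zs - cz)[None, None, :] ** 2
        )
        return np.sqrt(d2)


@dataclass(frozen=True)
class VoiMask:
    """A binary volume-of-interest mask congruent with an :class:`ImageVolume`."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("mask must be a 3D boolean array")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", spacing)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def volume(self) -> float:
        """Masked volume in mm^3."""
        return self.count * self.voxel_volume

    def extract(self, img: ImageVolume) -> np.ndarray:
        """Intensities of ``img`` inside the mask (1D array)."""
        if img.shape != self.mask.shape:
            raise ValueError(f"mask shape {self.mask.shape} does not match image shape {img.shape}")
        return img.values[self.mask]
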