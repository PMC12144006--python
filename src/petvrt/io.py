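"""File I/O and experiment configuration.

Volumes are read and written as NIfTI-1 (via nibabel) with the voxel
spacing in the header; autoradiography fields can also be exported as
plain text matrices.  Experiment configurations round-trip through a
single YAML file that, together with the code version, fully determines
a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .image import ImageVolume

__all__ = ["read_volume", "write_volume", "write_text_field", "ExperimentConfig"]


def read_volume(path) -> ImageVolume:
    """Load a NIfTI-1 volume, preserving values, spacing and origin."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"malformed header: non-positive voxel spacing {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(data, tuple(float(z) for z in zooms), origin)


def write_volume(img: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1 (float64, so values round-trip bit-exactly)."""
    affine = np.diag([*img.voxel_spacing, 1.0])
    affine[:3, 3] = img.origin
    nii = nib.Nifti1Image(img.values.astype(np.float64), affine)
    nii.header.set_data_dtype(np.float64)
    nib.save(nii, str(path))


def write_text_field(img: ImageVolume, path) -> None:
    """Export a 2D field (singleton third axis) as a plain text matrix."""
    if img.shape[2] != 1:
        raise ValueError("text export is for 2D fields with a singleton third axis")
    np.savetxt(str(path), img.values[:, :, 0], fmt="%.8g")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a wall-less vs. fillable VRT study."""

    diameters: list[float] = field(default_factory=lambda: [10.0, 13.0, 17.0, 22.0, 28.0, 37.0])
    sbr_targets: list[float] = field(default_factory=lambda: [2.0, 4.0, 6.0, 8.0, 10.0])
    sphere_activity: float = 10.0
    wall_thickness: float = 1.0
    wall_activity: float = 0.0
    psf_fwhm: float = 7.0
    noise_sigma: float = 0.0
    seed: int = 0
    oversample: int = 4
    grid_shape: list[int] = field(default_factory=lambda: [80, 80, 60])
    voxel_spacing: list[float] = field(default_factory=lambda: [1.0, 1.0, 2.0])
    connectivity: int = 6
    reference: str = "image_mean"  # or "true": A in (T-B)/(A-B)
    seed_voi_margin: float = 5.0
    profile_margin: float = 10.0
    sbr_voi_diameter: float = 20.0
    uniformity_voi_diameter: float = 27.0
    kl_bins: int = 64
    save_volumes: bool = False

    def __post_init__(self) -> None:
        if self.reference not in ("image_mean", "true"):
            raise ValueError(f"reference must be 'image_mean' or 'true', got {self.reference!r}")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
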