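"""Volume and Mask containers plus NIfTI-1 I/O (via nibabel)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "Mask", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A 3D scalar grid with voxel size and pass-through orientation metadata."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray, units: str | None = None) -> "Volume":
        """New Volume on this grid with the given data."""
        return Volume(data=data, voxel_size=self.voxel_size,
                      affine=self.affine.copy(),
                      units=self.units if units is None else units)


@dataclass
class Mask:
    """Boolean grid aligned to a Volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @classmethod
    def full(cls, shape) -> "Mask":
        return cls(np.ones(shape, dtype=bool))


def read_volume(path, apply_scaling: bool = True) -> Volume:
    """Read a 3D NIfTI-1 volume (plain or gzip).

    With ``apply_scaling`` the header slope/intercept are applied (the
    nibabel default float output); otherwise raw stored values are
    returned.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    if apply_scaling:
        data = np.asarray(img.get_fdata(dtype=np.float64))
    else:
        data = np.asarray(img.dataobj.get_unscaled())
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, voxel_size=zooms, affine=np.asarray(img.affine))


def write_volume(vol: Volume, path, dtype_policy: str = "float") -> None:
    """Write a Volume as NIfTI-1.

    ``dtype_policy``: "float" (32-bit float, the default), "flags" (8-bit
    unsigned integer, for validity-flag volumes).  Non-finite values are
    written as 0 so downstream tools never see NaN.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"output directory does not exist: {path.parent}")
    if dtype_policy == "float":
        data = np.nan_to_num(vol.data, nan=0.0, posinf=0.0, neginf=0.0)
        data = data.astype(np.float32)
    elif dtype_policy == "flags":
        data = np.asarray(vol.data).astype(np.uint8)
    else:
        raise ValueError(f"unknown dtype_policy {dtype_policy!r}")
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))
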