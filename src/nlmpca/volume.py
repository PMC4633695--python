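"""3D scalar volumes and NIfTI-1 I/O.

A :class:`Volume` is a 3rd-order real tensor ``data[i1, i2, i3]`` together
with its voxel geometry.  The first two axes index the in-plane dimensions
of a slice and the third axis enumerates slices, so the same object serves
interchangeably as the tensor ``X`` and as the slice set ``{X_1, ..., X_I3}``
consumed by the multilinear PCA stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["Volume", "VolumeError", "read_volume", "write_volume"]


class VolumeError(ValueError):
    """Raised for malformed volumes or unsupported on-disk images."""


@dataclass
class Volume:
    """A finite 3D intensity volume.

    Parameters
    ----------
    data
        Real-valued array of shape ``(I1, I2, I3)``; stored as float64.
    voxel_size_mm
        Physical edge lengths of one voxel, in millimetres.
    intensity_units
        Free-text description of the intensity scale (e.g. ``"arbitrary"``).
    affine
        Optional 4x4 voxel-to-world matrix carried through NIfTI round trips.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_units: str = "arbitrary"
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(
                f"volume data must be 3-dimensional, got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise VolumeError(f"empty volume axis in shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise VolumeError(f"voxel size must be 3 positive reals, got {vs}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        """Number of slices I3 (the sample axis of the MPCA stage)."""
        return self.data.shape[2]

    def slices(self) -> np.ndarray:
        """View of the volume as a stack of I3 matrices of shape I1 x I2."""
        return np.moveaxis(self.data, 2, 0)

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume carrying ``data`` but this volume's geometry/header."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


def read_volume(path: str | os.PathLike) -> Volume:
    """Load a 3D scalar NIfTI-1 image (.nii or .nii.gz).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    VolumeError
        If the image is not a 3D scalar volume or its datatype is not a
        real scalar type.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    shape = img.shape
    # Accept trailing singleton dimensions (some writers emit 181x217x181x1).
    if len(shape) > 3 and all(s == 1 for s in shape[3:]):
        shape = shape[:3]
        img = nib.Nifti1Image(
            np.asanyarray(img.dataobj).reshape(shape), img.affine, img.header
        )
    if len(img.shape) != 3:
        raise VolumeError(
            f"{path}: not a 3D scalar volume (shape {img.shape}); "
            "split 4D images into 3D volumes first"
        )
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.number) or np.iscomplexobj(data):
        raise VolumeError(f"{path}: unsupported datatype {data.dtype}")
    zooms = img.header.get_zooms()[:3]
    return Volume(
        data=data.astype(np.float64),
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=np.float64),
    )


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write ``vol`` as NIfTI-1, preserving affine and voxel size."""
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, os.fspath(path))
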