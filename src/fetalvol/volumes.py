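"""Core 3D image data model and NIfTI I/O.

A :class:`Volume` is a scalar 3D image on an isotropic grid; a
:class:`BinaryMask` is a {0,1} label image on the same kind of grid.  The
voxel edge length (``spacing_mm``) is the single geometric parameter: the
physical volume of one voxel is ``spacing_mm ** 3`` mm³, which is what turns
a voxel count into an intracranial volume in millilitres downstream.

Geometric conventions
---------------------
* Internal axis order is ``(x, y, z)`` = array axes ``(0, 1, 2)``; the
  physical position of voxel ``i`` along an axis is ``i * spacing_mm`` mm.
* NIfTI headers are honoured on read (spacing from the header zooms); files
  are written with a diagonal affine (identity orientation).
* Input files whose per-axis spacings differ by more than 1% are rejected
  rather than silently resampled.
* Intensity images are interpolated trilinearly; masks are interpolated and
  re-binarized at 0.5, so they stay strictly binary through every geometric
  operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "Volume",
    "BinaryMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
    "normalize_intensity",
    "resize_to",
]

#: spacings within this relative tolerance are treated as isotropic
ANISOTROPY_TOLERANCE = 0.01


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D image: voxel counts per axis and isotropic spacing."""

    shape: tuple[int, int, int]
    spacing_mm: float

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3:
            raise ValueError(f"expected 3D shape, got {shape}")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume S of one voxel in mm³."""
        return float(self.spacing_mm) ** 3

    @property
    def voxel_volume_ml(self) -> float:
        """Physical volume of one voxel in millilitres (1 mL = 1000 mm³)."""
        return self.voxel_volume_mm3 / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the image in mm."""
        return tuple(s * self.spacing_mm for s in self.shape)


class Volume:
    """A scalar 3D image with isotropic voxel spacing."""

    def __init__(self, data: np.ndarray, grid: VolumeGrid) -> None:
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {data.ndim}D data")
        if tuple(data.shape) != tuple(grid.shape):
            raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
        self.data = data
        self.grid = grid

    @property
    def spacing_mm(self) -> float:
        return self.grid.spacing_mm

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.grid)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Volume(shape={self.shape}, spacing={self.spacing_mm:g} mm)"


class BinaryMask:
    """A strictly binary {0,1} label image on a :class:`VolumeGrid`."""

    def __init__(self, data: np.ndarray, grid: VolumeGrid) -> None:
        arr = np.asarray(data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D data")
        if tuple(arr.shape) != tuple(grid.shape):
            raise ValueError(f"data shape {arr.shape} != grid shape {grid.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask not binary: found values {uniq[:10]}")
        self.data = arr.astype(np.uint8)
        self.grid = grid

    @property
    def spacing_mm(self) -> float:
        return self.grid.spacing_mm

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_voxels(self) -> int:
        """N — the number of labelled voxels."""
        return int(self.data.sum())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.grid)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BinaryMask(shape={self.shape}, spacing={self.spacing_mm:g} mm, "
            f"n={self.n_voxels})"
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_header(img: nib.Nifti1Image, path) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    mean = float(np.mean(zooms))
    if mean <= 0:
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    rel = (max(zooms) - min(zooms)) / mean
    if rel > ANISOTROPY_TOLERANCE:
        raise ValueError(
            f"{path}: anisotropic spacing {zooms} exceeds "
            f"{ANISOTROPY_TOLERANCE:.0%} tolerance; resample upstream"
        )
    return VolumeGrid(tuple(int(s) for s in img.shape[:3]), mean)


def _load_3d(path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        # tolerate trailing singleton dims (some exporters write (X,Y,Z,1))
        if len(img.shape) == 4 and img.shape[3] == 1:
            img = nib.Nifti1Image(
                np.asanyarray(img.dataobj)[..., 0], img.affine, img.header
            )
        else:
            raise ValueError(f"{path}: expected 3D volume, got shape {img.shape}")
    grid = _grid_from_header(img, path)
    return np.asanyarray(img.dataobj), grid


def read_volume(path) -> Volume:
    """Read a 3D intensity volume from a NIfTI file.

    Spacing is taken from the header zooms; anisotropic input beyond the 1%
    tolerance and non-3D input raise ``ValueError``.
    """
    data, grid = _load_3d(path)
    return Volume(np.asarray(data, dtype=np.float64), grid)


def read_mask(path) -> BinaryMask:
    """Read a binary mask from a NIfTI file; non-{0,1} values are an error."""
    data, grid = _load_3d(path)
    return BinaryMask(data, grid)


def _diag_affine(spacing: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spacing
    return aff


def write_volume(v: Volume, path) -> None:
    """Write an intensity volume as float32 NIfTI with a diagonal affine."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(v.data.astype(np.float32), _diag_affine(v.spacing_mm))
    img.header.set_zooms((v.spacing_mm,) * 3)
    nib.save(img, str(path))


def write_mask(m: BinaryMask, path) -> None:
    """Write a binary mask as uint8 NIfTI with a diagonal affine."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(m.data.astype(np.uint8), _diag_affine(m.spacing_mm))
    img.header.set_zooms((m.spacing_mm,) * 3)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Geometric operations
# ---------------------------------------------------------------------------

def _scale_resample(data: np.ndarray, out_shape, scale, order: int) -> np.ndarray:
    """Resample ``data`` on a new grid where output index ``o`` maps to input
    index ``o * scale`` (voxel-center aligned at the origin)."""
    matrix = np.diag(np.asarray(scale, dtype=float))
    return ndimage.affine_transform(
        data.astype(np.float64),
        matrix,
        output_shape=tuple(out_shape),
        order=order,
        mode="nearest",
    )


def resample_isotropic(obj, target_spacing: float):
    """Resample a Volume or BinaryMask to a new isotropic spacing.

    The physical extent is preserved within one voxel; intensities are
    interpolated trilinearly, masks re-binarized at 0.5.
    """
    if not target_spacing > 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    grid = obj.grid
    if any(s < 2 for s in grid.shape):
        raise ValueError(f"cannot resample degenerate axes, shape {grid.shape}")
    if np.isclose(target_spacing, grid.spacing_mm, rtol=1e-12, atol=0.0):
        return obj.copy()
    factor = grid.spacing_mm / target_spacing
    out_shape = tuple(max(1, int(round(s * factor))) for s in grid.shape)
    scale = (1.0 / factor,) * 3
    new_grid = VolumeGrid(out_shape, target_spacing)
    if isinstance(obj, BinaryMask):
        out = _scale_resample(obj.data, out_shape, scale, order=1)
        return BinaryMask((out > 0.5).astype(np.uint8), new_grid)
    out = _scale_resample(obj.data, out_shape, scale, order=1)
    return Volume(out, new_grid)


def normalize_intensity(v: Volume) -> Volume:
    """Affine min-max rescale of intensities to [0, 1].

    Constant volumes map to all zeros (the degenerate range has no
    information to preserve and 0/0 is avoided).
    """
    lo = float(v.data.min())
    hi = float(v.data.max())
    if hi == lo:
        return Volume(np.zeros_like(v.data), v.grid)
    return Volume((v.data - lo) / (hi - lo), v.grid)


def resize_to(obj, shape):
    """Interpolate to a requested voxel count, rescaling the spacing so the
    physical extent is preserved.

    For non-uniform axis scale factors the (isotropic) output spacing is the
    input spacing times the mean scale factor.  Masks are re-binarized at
    0.5 after interpolation.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 2 for s in shape):
        raise ValueError(f"target shape entries must be >= 2, got {shape}")
    grid = obj.grid
    if shape == tuple(grid.shape):
        return obj.copy()
    scale = tuple(si / so for si, so in zip(grid.shape, shape))
    new_spacing = grid.spacing_mm * float(np.mean(scale))
    new_grid = VolumeGrid(shape, new_spacing)
    if isinstance(obj, BinaryMask):
        out = _scale_resample(obj.data, shape, scale, order=1)
        return BinaryMask((out > 0.5).astype(np.uint8), new_grid)
    out = _scale_resample(obj.data, shape, scale, order=1)
    return Volume(out, new_grid)
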