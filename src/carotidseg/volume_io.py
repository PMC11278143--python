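"""NIfTI volume I/O and intensity/geometry preprocessing.

Axis convention (shared by every module): axis 0 indexes axial slices,
axes (1, 2) are the in-plane (row, column) coordinates.  On read, arbitrary
NIfTI orientations are first reoriented to canonical RAS and then transposed
so the superior axis becomes axis 0.

The preprocessing chain applied to raw scans is:

1. ``resample_isotropic`` — resample to 1 × 1 × 1 mm³ voxels (trilinear for
   images, nearest-neighbour for masks),
2. ``quantize_to_8bit`` — per-volume min–max rescale onto integers 0..255,
3. ``normalize_unit`` — divide by 255 so intensities live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "MaskVolume",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "quantize_to_8bit",
    "normalize_unit",
    "preprocess",
]


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as a scalar 3D volume."""


@dataclass
class Volume:
    """A scalar 3D image.

    Attributes
    ----------
    data
        Array of shape (slices, rows, cols); axis 0 is the axial direction.
    spacing
        Voxel size (sz, sy, sx) in millimetres, matching the axis order.
    dtype_tag
        One of ``uint16-like`` (raw integer intensities), ``uint8-like``
        (after quantization) or ``unit-float`` (after normalization, [0, 1]).
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    dtype_tag: str = "uint16-like"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise VolumeFormatError(f"degenerate shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"invalid spacing {self.spacing}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class MaskVolume:
    """A binary 3D label volume aligned with a :class:`Volume`.

    ``provenance`` records where the labels came from: ``weak-bbox`` (the
    initial bounding boxes), ``refined`` (a self-training round's output) or
    ``ground-truth`` (evaluation-only gold standard).
    """

    data: np.ndarray
    provenance: str = "weak-bbox"
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"mask must be 3D, got ndim={self.data.ndim}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeFormatError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.data.shape


def _load_canonical(path) -> tuple[np.ndarray, tuple]:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D scalar volume, got ndim={img.ndim}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.dtype.kind not in "uif":
        raise VolumeFormatError(f"{path}: non-scalar dtype {data.dtype}")
    sx, sy, sz = img.header.get_zooms()[:3]
    # canonical RAS axes are (x, y, z=superior); move the axial axis first
    data = np.transpose(data, (2, 1, 0))
    return data, (float(sz), float(sy), float(sx))


def read_volume(path) -> Volume:
    """Read a NIfTI-1 file as a :class:`Volume` (axis 0 = axial slices)."""
    data, spacing = _load_canonical(path)
    tag = "unit-float" if data.dtype.kind == "f" and np.nanmax(np.abs(data), initial=0) <= 1.0 else "uint16-like"
    return Volume(data=data.astype(np.float64), spacing=spacing, dtype_tag=tag)


def read_mask(path, provenance: str = "weak-bbox") -> MaskVolume:
    """Read a NIfTI-1 file as a binary :class:`MaskVolume`."""
    data, spacing = _load_canonical(path)
    return MaskVolume(data=(data > 0.5).astype(np.uint8), provenance=provenance, spacing=spacing)


def write_volume(vol, path) -> None:
    """Write a Volume or MaskVolume to NIfTI-1, inverting the read transpose."""
    data = vol.data
    if isinstance(vol, MaskVolume):
        data = data.astype(np.uint8)
    sz, sy, sx = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def resample_isotropic(v, target_mm: float = 1.0, kind: str = "image"):
    """Resample a volume to isotropic ``target_mm`` voxels.

    Output shape per axis is round(extent_mm / target_mm).  Images use
    trilinear interpolation; masks use nearest-neighbour and stay binary.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if kind not in ("image", "mask"):
        raise ValueError(f"kind must be 'image' or 'mask', got {kind!r}")
    spacing = np.asarray(v.spacing, dtype=float)
    if np.allclose(spacing, target_mm):
        return v
    zoom = spacing / target_mm
    order = 1 if kind == "image" else 0
    out = ndimage.zoom(np.asarray(v.data, dtype=float), zoom, order=order,
                       mode="nearest", grid_mode=False)
    new_spacing = (target_mm,) * 3
    if isinstance(v, MaskVolume):
        return MaskVolume(data=(out > 0.5).astype(np.uint8),
                          provenance=v.provenance, spacing=new_spacing)
    return replace(v, data=out, spacing=new_spacing)


def quantize_to_8bit(v: Volume) -> Volume:
    """Linearly rescale [per-volume min, max] onto integers 0..255.

    Rounding is half-up; a constant volume maps to all zeros.
    """
    data = np.asarray(v.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = np.floor(255.0 * (data - lo) / (hi - lo) + 0.5)
    return replace(v, data=out, dtype_tag="uint8-like")


def normalize_unit(v: Volume) -> Volume:
    """Divide 8-bit intensities by 255 so values lie in [0, 1]."""
    return replace(v, data=np.asarray(v.data, dtype=np.float64) / 255.0,
                   dtype_tag="unit-float")


def preprocess(v: Volume, target_mm: float = 1.0) -> Volume:
    """Full image chain: isotropic resample → 8-bit quantize → unit normalize."""
    return normalize_unit(quantize_to_8bit(resample_isotropic(v, target_mm, "image")))
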