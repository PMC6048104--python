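"""Volume and label-map I/O with a single geometry convention.

All arrays are held in (x, y, z) index order with x the fastest axis, spacing
in mm, and intensities as float64. Supported formats: NIfTI-1 (.nii/.nii.gz)
through nibabel and MetaImage (.mhd/.mha) through a minimal built-in codec.
Volumes are assumed axis-aligned; oblique direction matrices are rejected
unless explicitly allowed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from shapecut import _metaimage

__all__ = [
    "Volume",
    "LabelVolume",
    "read_volume",
    "read_label_volume",
    "write_volume",
    "check_same_grid",
    "GridMismatchError",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _validate_geometry(spacing, origin, shape) -> tuple[tuple, tuple]:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3 or len(shape) != 3:
        raise ValueError("spacing, origin and shape must have length 3")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"voxel spacing must be strictly positive and finite, got {spacing}")
    if not all(int(n) > 0 for n in shape):
        raise ValueError(f"shape must be positive, got {shape}")
    return spacing, origin


@dataclass
class Volume:
    """A 3D scalar grid: intensities plus physical geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        self.spacing, self.origin = _validate_geometry(self.spacing, self.origin, self.data.shape)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains NaN or Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D integer label grid sharing a Volume's geometry (0 = background)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"LabelVolume data must be 3D, got {data.ndim}D")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(np.isfinite(data)) or not np.all(data == np.round(data)):
                raise ValueError("label data must be integral")
            data = data.astype(np.int32)
        if data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = data.astype(np.int32, copy=False)
        self.spacing, self.origin = _validate_geometry(self.spacing, self.origin, data.shape)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def label_set(self) -> frozenset:
        return frozenset(int(v) for v in np.unique(self.data))

    def binary(self) -> np.ndarray:
        """Foreground mask (any nonzero label)."""
        return self.data > 0


def check_same_grid(a, b, rtol: float = 1e-6) -> bool:
    """True iff shapes are equal and spacings agree within relative tolerance."""
    if a.shape != b.shape:
        return False
    sa, sb = np.asarray(a.spacing), np.asarray(b.spacing)
    return bool(np.allclose(sa, sb, rtol=rtol, atol=0.0))


def require_same_grid(a, b, what: str = "input") -> None:
    if not check_same_grid(a, b):
        raise GridMismatchError(
            f"{what}: grid mismatch (shape {a.shape} / spacing {a.spacing} vs "
            f"shape {b.shape} / spacing {b.spacing})"
        )


def _is_axis_aligned(mat: np.ndarray, tol: float = 1e-4) -> bool:
    off = mat - np.diag(np.diag(mat))
    return bool(np.all(np.abs(off) <= tol * max(1.0, np.abs(mat).max())) and np.all(np.diag(mat) > 0))


def _read_raw(path: str, allow_oblique: bool):
    if not os.path.exists(path):
        raise OSError(f"no such file: {path}")
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(path)
        except Exception as exc:  # noqa: BLE001 - re-raise with path context
            raise OSError(f"unreadable NIfTI file {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D image, got {data.ndim}D: {path}")
        affine = np.asarray(img.affine, dtype=float)
        rot = affine[:3, :3]
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if not _is_axis_aligned(rot) and not allow_oblique:
            raise ValueError(
                f"non-axis-aligned direction matrix in {path}; "
                "pass allow_oblique=True to accept the voxel grid as-is"
            )
        origin = tuple(float(t) for t in affine[:3, 3])
        return np.asarray(data), spacing, origin
    if lower.endswith((".mhd", ".mha")):
        try:
            return _metaimage.read(path)
        except OSError:
            raise
        except ValueError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise OSError(f"unreadable MetaImage file {path}: {exc}") from exc
    raise ValueError(f"unsupported image format (want .nii/.nii.gz/.mhd/.mha): {path}")


def read_volume(path: str, allow_oblique: bool = False) -> Volume:
    """Read an intensity volume; geometry comes from the header.

    Raises OSError for unreadable files and ValueError for non-3D images,
    non-positive spacing, or NaN/Inf intensities.
    """
    data, spacing, origin = _read_raw(path, allow_oblique)
    return Volume(data=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def read_label_volume(path: str, allow_oblique: bool = False) -> LabelVolume:
    """Read an integer label volume (values must be integral non-negative)."""
    data, spacing, origin = _read_raw(path, allow_oblique)
    return LabelVolume(data=data, spacing=spacing, origin=origin)


def write_volume(v, path: str) -> None:
    """Write a Volume (float32 on disk) or LabelVolume (int16) to NIfTI or MetaImage."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise OSError(f"parent directory does not exist: {parent}")
    if isinstance(v, LabelVolume):
        data = v.data.astype(np.int16)
    else:
        data = v.data.astype(np.float32)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(v.spacing) + [1.0])
        affine[:3, 3] = v.origin
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(v.spacing)
        nib.save(img, path)
    elif lower.endswith((".mhd", ".mha")):
        _metaimage.write(path, data, v.spacing, v.origin)
    else:
        raise ValueError(f"unsupported image format (want .nii/.nii.gz/.mhd/.mha): {path}")
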