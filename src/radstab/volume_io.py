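"""Volume and mask containers, NIfTI/NRRD I/O, intensity preparation.

Arrays are stored in (x, y, z) index order; world coordinates follow
``world = origin_mm + index * spacing_mm`` with 0-based indices and no axis
reordering.  Files whose orientation matrix is not axis-aligned are rejected
rather than silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeGrid",
    "MaskVolume",
    "GeometryError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "normalize_intensities",
    "crop_to_mask",
    "check_aligned",
]

#: tolerance (mm) for geometry equality between a volume and its mask
GEOMETRY_ATOL_MM = 1e-3


class GeometryError(ValueError):
    """Raised when a volume/mask pair disagree in shape, spacing or origin."""


@dataclass
class VolumeGrid:
    """A 3D scalar image (HU) with voxel spacing and origin in mm."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.spacing_mm)) or np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """Same grid geometry, new scalar field."""
        return VolumeGrid(values, self.spacing_mm.copy(), self.origin_mm.copy())


@dataclass
class MaskVolume:
    """A binary 3D mask on the same grid as its paired :class:`VolumeGrid`."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.values.ndim}")
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "MaskVolume":
        return MaskVolume(values, self.spacing_mm.copy(), self.origin_mm.copy())


def check_aligned(v: VolumeGrid | MaskVolume, m: VolumeGrid | MaskVolume) -> None:
    """Raise :class:`GeometryError` naming the first mismatching field."""
    if v.values.shape != m.values.shape:
        raise GeometryError(
            f"shape mismatch: {v.values.shape} vs {m.values.shape}"
        )
    if not np.allclose(v.spacing_mm, m.spacing_mm, atol=GEOMETRY_ATOL_MM):
        raise GeometryError(
            f"spacing mismatch: {v.spacing_mm} vs {m.spacing_mm}"
        )
    if not np.allclose(v.origin_mm, m.origin_mm, atol=GEOMETRY_ATOL_MM):
        raise GeometryError(f"origin mismatch: {v.origin_mm} vs {m.origin_mm}")


# ---------------------------------------------------------------------------
# File I/O (NIfTI-1 and NRRD, via SimpleITK)
# ---------------------------------------------------------------------------

_AXIS_ALIGNED_ATOL = 1e-6


def _to_sitk(values: np.ndarray, spacing_mm, origin_mm) -> sitk.Image:
    # SimpleITK array layout is (z, y, x); ours is (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing_mm))
    img.SetOrigin(tuple(float(o) for o in origin_mm))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=_AXIS_ALIGNED_ATOL):
        raise GeometryError(
            "non-axis-aligned orientation matrix; resampling is out of scope — "
            f"direction={direction.tolist()}"
        )
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return values, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())


def write_volume(v: VolumeGrid, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD (.nrrd), by extension."""
    path = Path(path)
    sitk.WriteImage(_to_sitk(v.values.astype(np.float64), v.spacing_mm, v.origin_mm), str(path))
    return path


def write_mask(m: MaskVolume, path: str | Path) -> Path:
    """Write a mask as unsigned 8-bit {0,1}."""
    path = Path(path)
    sitk.WriteImage(
        _to_sitk(m.values.astype(np.uint8), m.spacing_mm, m.origin_mm), str(path)
    )
    return path


def read_volume(path: str | Path) -> VolumeGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    values, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return VolumeGrid(values.astype(np.float64), spacing, origin)


def read_mask(path: str | Path) -> MaskVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    values, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return MaskVolume(values > 0, spacing, origin)


# ---------------------------------------------------------------------------
# Intensity preparation
# ---------------------------------------------------------------------------

NORMALIZE_MODES = ("none", "unit_range", "zscore")


def normalize_intensities(v: VolumeGrid, mode: str = "none") -> VolumeGrid:
    """Whole-volume intensity normalization.

    ``none`` returns the input unchanged (the default for CT: HU are already
    calibrated); ``unit_range`` maps [min, max] to [0, 1]; ``zscore`` centers
    to mean 0, sd 1.  Constant volumes cannot be rescaled and raise.
    """
    if mode not in NORMALIZE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {NORMALIZE_MODES}")
    if mode == "none":
        return v
    x = v.values
    if mode == "unit_range":
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise ValueError("constant volume: unit_range normalization is degenerate")
        return v.with_values((x - lo) / (hi - lo))
    sd = float(x.std())
    if sd == 0.0:
        raise ValueError("constant volume: zscore normalization is degenerate")
    return v.with_values((x - x.mean()) / sd)


def crop_to_mask(
    v: VolumeGrid, m: MaskVolume, pad_voxels: int = 1
) -> tuple[VolumeGrid, MaskVolume]:
    """Crop both arrays to the mask bounding box plus ``pad_voxels``.

    All feature definitions depend only on in-mask voxels and the grid
    geometry, so extraction on the cropped pair equals extraction on the full
    pair.  The origin is shifted so world coordinates are preserved.
    """
    check_aligned(v, m)
    if m.n_foreground == 0:
        raise ValueError("empty mask: nothing to crop to")
    lo = []
    hi = []
    for axis in range(3):
        proj = np.any(m.values, axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lo.append(max(0, idx[0] - pad_voxels))
        hi.append(min(m.values.shape[axis], idx[-1] + 1 + pad_voxels))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    origin = v.origin_mm + np.array(lo) * v.spacing_mm
    return (
        VolumeGrid(v.values[sl].copy(), v.spacing_mm.copy(), origin),
        MaskVolume(m.values[sl].copy(), m.spacing_mm.copy(), origin.copy()),
    )
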