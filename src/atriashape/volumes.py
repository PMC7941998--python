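"""Volume containers, mask I/O, resampling and template selection.

The left-atrium models handled by this package are 3D binary voxel masks on
axis-aligned grids with millimetre spacing.  All downstream stages (atlas
registration, signed-distance statistics, deformation features) consume the
:class:`BinaryMask` defined here.  World coordinates follow the convention

    world(i, j, k) = origin + (i * sx, j * sy, k * sz)

with 0-based indices and arrays stored in (x, y, z) axis order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

logger = logging.getLogger("atriashape")

Vec3 = tuple[float, float, float]

_MASK_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


class VolumeError(ValueError):
    """Invalid volume data or header."""


class EmptyForegroundError(VolumeError):
    """Mask contains no foreground voxels."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing and origin (mm)."""

    data: np.ndarray
    spacing: Vec3
    origin: Vec3 = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.data.ndim != 3:
            raise VolumeError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise VolumeError(f"grid must be >= 2 voxels per axis, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.data.shape[a])
            for a in range(3)
        )

    def grid_points(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (*grid, 3)."""
        xs, ys, zs = self.axis_coords()
        return np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class BinaryMask(ImageVolume):
    """A binary segmentation mask (values in {0, 1}, uint8 storage)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeError(f"mask values must be 0/1, found {vals[:8]}")
        self.data = self.data.astype(np.uint8)

    def validate(self, margin: int = 2) -> None:
        """Enforce mask invariants: nonempty, single 26-connected component,
        foreground clear of the grid boundary by ``margin`` voxels."""
        if not self.data.any():
            raise EmptyForegroundError("mask has empty foreground")
        _, n_comp = ndimage.label(self.data, structure=np.ones((3, 3, 3)))
        if n_comp != 1:
            raise VolumeError(f"mask has {n_comp} 26-connected components, expected 1")
        idx = np.argwhere(self.data)
        lo = idx.min(axis=0)
        hi = np.array(self.data.shape) - 1 - idx.max(axis=0)
        if lo.min() < margin or hi.min() < margin:
            raise VolumeError(
                f"foreground margin {min(lo.min(), hi.min())} voxels < required {margin}"
            )

    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class CohortAtlas:
    """A cohort of masks co-registered onto one member's (the template's) grid."""

    members: list[BinaryMask]
    labels: np.ndarray
    template_index: int
    alignment_mode: str = "affine"
    # (original index, reason) of members dropped at a registration gate
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.members) != len(self.labels):
            raise VolumeError("labels must align with members")
        if not 0 <= self.template_index < len(self.members):
            raise VolumeError(f"template_index {self.template_index} out of range")
        tmpl = self.members[self.template_index]
        for i, m in enumerate(self.members):
            if not m.same_grid(tmpl):
                raise VolumeError(f"member {i} is not on the template grid")


# ---------------------------------------------------------------------------
# SimpleITK conversion helpers.  SimpleITK arrays are indexed (z, y, x); the
# package convention is (x, y, z), hence the transposes.
# ---------------------------------------------------------------------------

def to_sitk(vol: ImageVolume, dtype=None) -> sitk.Image:
    data = vol.data if dtype is None else vol.data.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def from_sitk(img: sitk.Image, as_mask: bool = False) -> ImageVolume:
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    if as_mask:
        return BinaryMask((data > 0.5).astype(np.uint8), spacing, origin)
    return ImageVolume(data, spacing, origin)


def _check_axis_aligned(img: sitk.Image, path: str) -> None:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-3):
        raise VolumeError(
            f"{path}: non-identity orientation matrix {direction.tolist()}; "
            "only axis-aligned volumes are supported"
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def read_mask(path: str, cleanup: bool = True) -> BinaryMask:
    """Read a binary mask from a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) file.

    Voxels are binarized at 0.5.  When ``cleanup`` is on, all but the largest
    26-connected foreground component are dropped (with a warning).
    """
    spath = str(path)
    if not any(spath.endswith(ext) for ext in _MASK_EXTENSIONS):
        raise VolumeError(f"{spath}: unsupported extension (need {_MASK_EXTENSIONS})")
    try:
        img = sitk.ReadImage(spath)
    except RuntimeError as exc:  # sitk wraps I/O failures in RuntimeError
        raise VolumeError(f"unreadable volume file {spath}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeError(f"{spath}: expected a 3D volume, got {img.GetDimension()}D")
    _check_axis_aligned(img, spath)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    binary = (np.asarray(data, dtype=np.float64) >= 0.5).astype(np.uint8)
    if not binary.any():
        raise EmptyForegroundError(f"{spath}: empty foreground")
    if cleanup:
        lab, n_comp = ndimage.label(binary, structure=np.ones((3, 3, 3)))
        if n_comp > 1:
            sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, n_comp + 1))
            keep = int(np.argmax(sizes)) + 1
            logger.warning(
                "%s: dropping %d smaller foreground component(s)", spath, n_comp - 1
            )
            binary = (lab == keep).astype(np.uint8)
    return BinaryMask(binary, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_mask(mask: BinaryMask, path: str) -> None:
    """Write a mask as an unsigned 8-bit NIfTI or MetaImage volume."""
    sitk.WriteImage(to_sitk(mask, dtype=np.uint8), str(path))


def resample_isotropic(mask: BinaryMask, target_mm: float = 1.0) -> BinaryMask:
    """Resample a mask to isotropic ``target_mm`` spacing (nearest neighbour).

    Foreground volume is preserved to within a few percent for smooth shapes.
    Returns the input unchanged (same object) when already at target spacing.
    """
    if target_mm <= 0:
        raise VolumeError(f"target spacing must be > 0, got {target_mm}")
    if np.allclose(mask.spacing, (target_mm,) * 3):
        return mask
    img = to_sitk(mask, dtype=np.uint8)
    new_size = [
        int(np.ceil(n * s / target_mm)) for n, s in zip(mask.data.shape, mask.spacing)
    ]
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        sitk.sitkNearestNeighbor,
        img.GetOrigin(),
        (target_mm,) * 3,
        img.GetDirection(),
        0,
        sitk.sitkUInt8,
    )
    return from_sitk(out, as_mask=True)


def mask_volume_ml(mask: BinaryMask) -> float:
    """Foreground volume in cm^3 (= mL): voxel count x voxel volume / 1000."""
    return mask.foreground_count() * mask.voxel_volume_mm3 / 1000.0


def select_template(masks: list[BinaryMask]) -> int:
    """Index of the median-volume mask.

    For even counts the lower median is used; exact volume ties resolve to the
    lowest index (stable sort).  This member serves as the atlas template.
    """
    if not masks:
        raise VolumeError("cannot select a template from an empty cohort")
    volumes = np.array([mask_volume_ml(m) for m in masks])
    order = np.argsort(volumes, kind="stable")
    median_vol = volumes[order[(len(masks) - 1) // 2]]
    return int(np.flatnonzero(volumes == median_vol)[0])
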