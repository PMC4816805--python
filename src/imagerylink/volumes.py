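"""Volume data model, NIfTI I/O, Gaussian smoothing, masking, and sphere ROIs.

World coordinates are millimeters in an MNI-like axis-aligned frame: the
center of voxel ``(i, j, k)`` sits at ``origin_mm + index * voxel_size_mm``.
All ROI membership decisions are evaluated at voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    EmptyMaskError,
    GridMismatchError,
    UnsupportedOrientationError,
    ValidationError,
)

# FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

VOLUME_KINDS = ("gray_matter", "t", "F", "mask", "generic")


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned 3D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along x, y, z.
    voxel_size_mm
        Edge length of a voxel along each axis (isotropic 1.5 mm for the
        structural stream, 2.0 mm for the functional stream).
    origin_mm
        World coordinate of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError(
                f"voxel sizes must be 3 positive reals, got {self.voxel_size_mm}"
            )
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    @classmethod
    def isotropic(
        cls, shape: Sequence[int], voxel_mm: float, centered: bool = True
    ) -> "VoxelGrid":
        """Isotropic grid, optionally with the world origin at the grid center."""
        shape = tuple(int(s) for s in shape)
        if centered:
            origin = tuple(-(s - 1) / 2.0 * voxel_mm for s in shape)
        else:
            origin = (0.0, 0.0, 0.0)
        return cls(shape, (voxel_mm,) * 3, origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, RAS-like)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for (..., 3) index arrays."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.voxel_size_mm)

    def world_to_index(self, world_mm: Sequence[float]) -> np.ndarray:
        """Fractional voxel index of a world coordinate."""
        w = np.asarray(world_mm, dtype=float)
        return (w - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.voxel_size_mm, self.origin_mm))


@dataclass
class VolumeMap:
    """A scalar 3D image on a :class:`VoxelGrid`.

    ``kind`` tags the payload: modulated gray-matter volume, a t or F
    statistic map, or a binary mask.
    """

    grid: VoxelGrid
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in VOLUME_KINDS:
            raise ValidationError(f"unknown volume kind {self.kind!r}")
        if self.kind == "gray_matter" and np.any(self.values < 0):
            raise ValidationError("gray_matter volumes must be nonnegative")
        if self.kind == "mask":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError("mask volumes must be binary (0/1)")

    def copy(self) -> "VolumeMap":
        return VolumeMap(self.grid, self.values.copy(), self.kind)


@dataclass
class SphereMask:
    """Spherical ROI materialized as voxel indices on a grid.

    A voxel belongs to the sphere iff the Euclidean distance from its center
    to ``center_mm`` is <= ``radius_mm`` (inclusive boundary). With a 12 mm
    radius on a 2 mm isotropic grid and the center on a voxel center this
    yields 925 voxels.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    grid: VoxelGrid
    voxel_indices: np.ndarray = field(repr=False)  # (n, 3) int, lexicographic order

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])

    def flat_indices(self) -> np.ndarray:
        """Raveled (C-order) indices into a volume of this grid's shape."""
        return np.ravel_multi_index(self.voxel_indices.T, self.grid.shape)

    def to_volume(self) -> VolumeMap:
        vol = np.zeros(self.grid.shape, dtype=np.uint8)
        vol[tuple(self.voxel_indices.T)] = 1
        return VolumeMap(self.grid, vol, kind="mask")


def make_sphere_mask(
    center_mm: Sequence[float], radius_mm: float, grid: VoxelGrid
) -> SphereMask:
    """Materialize a sphere ROI: voxels whose centers lie within radius (inclusive).

    Raises
    ------
    EmptyMaskError
        If no voxel center falls inside the sphere.
    """
    if radius_mm < 0:
        raise ValidationError(f"radius must be >= 0, got {radius_mm}")
    center = np.asarray(center_mm, dtype=float)
    vox = np.asarray(grid.voxel_size_mm)
    # candidate bounding box in index space, clipped to the grid
    lo = np.maximum(np.floor(grid.world_to_index(center - radius_mm)).astype(int), 0)
    hi = np.minimum(
        np.ceil(grid.world_to_index(center + radius_mm)).astype(int),
        np.asarray(grid.shape) - 1,
    )
    if np.any(lo > hi):
        raise EmptyMaskError(
            f"sphere at {tuple(center)} r={radius_mm} lies outside the grid"
        )
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    centers = grid.index_to_world(idx)
    inside = np.sqrt(((centers - center) ** 2).sum(axis=1)) <= radius_mm
    idx = idx[inside]
    if idx.shape[0] == 0:
        raise EmptyMaskError(
            f"sphere at {tuple(center)} r={radius_mm} contains no voxel centers"
        )
    # lexicographic order for deterministic downstream vector extraction
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    return SphereMask(tuple(center), float(radius_mm), grid, idx[order])


def gaussian_smooth(vol: VolumeMap, fwhm_mm: float, mode: str = "constant") -> VolumeMap:
    """Separable Gaussian smoothing with an isotropic FWHM given in millimeters.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted to voxel units.
    ``mode='constant'`` (zero padding) is the default boundary treatment.
    """
    if fwhm_mm < 0:
        raise ValidationError(f"FWHM must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol.copy()
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / v for v in vol.grid.voxel_size_mm]
    out = ndimage.gaussian_filter(np.asarray(vol.values, dtype=float), sigmas, mode=mode)
    kind = vol.kind if vol.kind != "mask" else "generic"
    return VolumeMap(vol.grid, out, kind)


def absolute_mask(gm_maps: Iterable[VolumeMap], threshold: float = 0.05) -> VolumeMap:
    """Binary analysis mask: keep a voxel iff *every* subject's value >= threshold.

    This is the SPM-style absolute threshold used to trim edge voxels between
    tissue classes before voxelwise regression.
    """
    maps = list(gm_maps)
    if not maps:
        raise ValidationError("need at least one map")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise GridMismatchError("all maps must share one grid")
    stack = np.stack([m.values for m in maps])
    keep = (stack >= threshold).all(axis=0).astype(np.uint8)
    return VolumeMap(grid, keep, kind="mask")


def _grid_from_affine(affine: np.ndarray, shape: Sequence[int]) -> VoxelGrid:
    lin = affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
        raise UnsupportedOrientationError(
            "only axis-aligned (diagonal) affines are supported"
        )
    voxel = np.diag(lin)
    if np.any(voxel <= 0):
        raise UnsupportedOrientationError(
            f"voxel sizes must be positive along all axes, got {tuple(voxel)}"
        )
    return VoxelGrid(tuple(shape[:3]), tuple(voxel), tuple(affine[:3, 3]))


def read_volume(path) -> VolumeMap:
    """Read a 3D NIfTI-1 file into a :class:`VolumeMap` (kind 'generic')."""
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"expected 3D volume, got shape {data.shape}")
    return VolumeMap(grid, np.asarray(data), kind="generic")


def write_volume(vol: VolumeMap, path) -> None:
    """Write a :class:`VolumeMap` as NIfTI-1 (float32; masks as uint8)."""
    dtype = np.uint8 if vol.kind == "mask" else np.float32
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=dtype), vol.grid.affine())
    nib.save(img, str(path))


def read_volume_stack(path) -> list[VolumeMap]:
    """Read a 4D NIfTI as a list of 3D maps (subject or condition stack)."""
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError(f"expected 4D volume, got shape {data.shape}")
    return [VolumeMap(grid, np.asarray(data[..., i]), "generic") for i in range(data.shape[3])]


def write_volume_stack(maps: Sequence[VolumeMap], path) -> None:
    """Write a list of 3D maps sharing one grid as a 4D float32 NIfTI."""
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise GridMismatchError("all maps in a stack must share one grid")
    data = np.stack([np.asarray(m.values, dtype=np.float32) for m in maps], axis=-1)
    nib.save(nib.Nifti1Image(data, grid.affine()), str(path))
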