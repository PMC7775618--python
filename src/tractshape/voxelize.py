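"""Voxelization of streamline bundles and binary-volume morphology.

A bundle is converted to a set of unique integer voxel coordinates by
rounding point coordinates onto a refined grid: coordinates are divided
by the source voxel size, multiplied by an integer ``scale`` (default 2,
i.e. a half-resolution grid), and rounded to the nearest integer.  The
effective spacing of that grid is ``voxel_size_mm / scale``; per-voxel
volume is the cube of the spacing, so scale 2 makes each voxel 8x
smaller than the source grid's.  All area/volume descriptors consume
this bookkeeping through :class:`VoxelSet`.

Rounding is half-away-from-zero (standard voxel binning), so a point
sits in the voxel whose centre is nearest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .streamline_io import TrajectoryBundle, resample_max_step

__all__ = [
    "VoxelSet",
    "BinaryVolume",
    "round_to_voxel",
    "voxelize_points",
    "voxelize_bundle",
    "to_binary_volume",
    "surface_voxels",
    "connected_components",
]


def round_to_voxel(x: np.ndarray) -> np.ndarray:
    """Round half away from zero to the nearest integer (vectorized)."""
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x)).astype(np.int64)


@dataclass(frozen=True)
class VoxelSet:
    """Unique integer voxel coordinates with grid-scale bookkeeping.

    ``coords`` live on the refined grid: a coordinate ``c`` (mm) maps to
    voxel ``round(c * scale / base_voxel_size_mm)``.
    """

    coords: np.ndarray  # (N, 3) int
    scale: int = 2
    base_voxel_size_mm: float = 1.0

    def __post_init__(self):
        coords = np.asarray(self.coords)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must be a non-empty (N, 3) array")
        coords = np.unique(coords.astype(np.int64), axis=0)
        object.__setattr__(self, "coords", coords)
        if not self.effective_spacing_mm > 0:
            raise ValueError("effective spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def effective_spacing_mm(self) -> float:
        return self.base_voxel_size_mm / self.scale

    @property
    def voxel_volume_mm3(self) -> float:
        return self.effective_spacing_mm**3

    def centers_mm(self) -> np.ndarray:
        """Voxel centre coordinates back in mm space."""
        return self.coords * self.effective_spacing_mm


@dataclass(frozen=True)
class BinaryVolume:
    """Dense 0/1 grid spanning the bounding box of a :class:`VoxelSet`."""

    data: np.ndarray  # bool, 3D
    origin: np.ndarray  # (3,) int voxel coordinate of data[0, 0, 0]
    scale: int = 2
    base_voxel_size_mm: float = 1.0

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def effective_spacing_mm(self) -> float:
        return self.base_voxel_size_mm / self.scale

    def to_voxel_set(self) -> VoxelSet:
        coords = np.argwhere(self.data) + self.origin
        return VoxelSet(coords, scale=self.scale, base_voxel_size_mm=self.base_voxel_size_mm)


def voxelize_points(
    points: np.ndarray, base_voxel_size_mm: float = 1.0, scale: int = 2
) -> np.ndarray:
    """Map mm coordinates to (non-unique) integer voxel coordinates."""
    return round_to_voxel(np.asarray(points, float) * scale / base_voxel_size_mm)


def voxelize_bundle(bundle: TrajectoryBundle, scale: int = 2) -> VoxelSet:
    """Bundle -> unique voxel coordinates on the refined grid.

    Streamlines are first resampled so consecutive gaps are smaller than
    the effective spacing, which guarantees each streamline's voxel trace
    is connected.
    """
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    spacing = bundle.voxel_size_mm / scale
    resampled = resample_max_step(bundle, spacing)
    pts = np.vstack(resampled.streamlines)
    coords = voxelize_points(pts, bundle.voxel_size_mm, scale)
    return VoxelSet(coords, scale=scale, base_voxel_size_mm=bundle.voxel_size_mm)


def to_binary_volume(vox: VoxelSet, pad: int = 1) -> BinaryVolume:
    """Densify a voxel set into a padded 0/1 volume.

    One voxel of zero padding (default) guarantees that foreground voxels
    on the bounding-box boundary still see zero-valued neighbours, so
    surface detection needs no special border handling.
    """
    lo = vox.coords.min(axis=0) - pad
    hi = vox.coords.max(axis=0) + pad
    shape = tuple(hi - lo + 1)
    data = np.zeros(shape, dtype=bool)
    idx = vox.coords - lo
    data[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return BinaryVolume(data, origin=lo, scale=vox.scale, base_voxel_size_mm=vox.base_voxel_size_mm)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def surface_voxels(vol: BinaryVolume, connectivity: int = 6) -> VoxelSet:
    """Foreground voxels with at least one zero-valued neighbour.

    Computed as the erosion residue: the interior is the binary erosion
    of the volume (border treated as zero), and the surface is everything
    foreground that is not interior.
    """
    if vol.n_foreground == 0:
        raise ValueError("empty volume has no surface")
    interior = ndimage.binary_erosion(
        vol.data, structure=_structure(connectivity), border_value=0
    )
    surface = vol.data & ~interior
    coords = np.argwhere(surface) + vol.origin
    return VoxelSet(coords, scale=vol.scale, base_voxel_size_mm=vol.base_voxel_size_mm)


def connected_components(vox: VoxelSet, connectivity: int = 26) -> list[VoxelSet]:
    """Partition a voxel set into connected components, largest first.

    Ties in size are broken by the smallest lexicographic minimum
    coordinate, making the ordering deterministic.
    """
    vol = to_binary_volume(vox)
    labels, n = ndimage.label(vol.data, structure=_structure(connectivity))
    comps = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab) + vol.origin
        comps.append(VoxelSet(coords, scale=vox.scale, base_voxel_size_mm=vox.base_voxel_size_mm))
    # coords are row-sorted by construction, so coords[0] is the lex-min voxel
    comps.sort(key=lambda c: (-c.n_voxels, tuple(c.coords[0])))
    return comps
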