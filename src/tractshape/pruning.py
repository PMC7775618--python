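"""Topology-informed pruning (TIP).

White-matter pathways form bundles or sheets, so a genuine streamline
travels through voxels shared with many of its neighbours.  A noisy or
spurious streamline, by contrast, wanders through voxels that few other
streamlines touch.  TIP exploits this: it computes the voxel-wise
streamline density (how many distinct streamlines touch each voxel),
removes every streamline that passes through a low-density voxel, and
repeats — by default for up to 20 iterations, stopping early at a fixed
point.  The density cutoff defaults to 1 (voxels supported by a single
streamline).

Density is computed on the source voxel grid (scale 1); streamlines are
resampled to sub-voxel steps first, so a streamline's voxel trace has
no gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .streamline_io import TrajectoryBundle, resample_max_step
from .voxelize import voxelize_points

__all__ = ["DensityMap", "BundleEmptiedError", "density_map", "tip_prune"]


class BundleEmptiedError(RuntimeError):
    """A pruning pass would remove every remaining streamline."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(
            f"pruning iteration {iteration} would empty the bundle; "
            "the bundle is too thin for this density threshold "
            "(reduce iterations or pass keep_last=True)"
        )


@dataclass(frozen=True)
class DensityMap:
    """Per-voxel count of distinct streamlines, dense grid + origin."""

    counts: np.ndarray  # int, 3D
    origin: np.ndarray  # (3,) int
    voxel_size_mm: float

    def count_at(self, coords: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(coords) - self.origin
        return self.counts[idx[:, 0], idx[:, 1], idx[:, 2]]


def _streamline_voxel_sets(bundle: TrajectoryBundle) -> list[np.ndarray]:
    """Unique voxel coordinates touched by each streamline (scale-1 grid)."""
    resampled = resample_max_step(bundle, bundle.voxel_size_mm)
    return [
        np.unique(voxelize_points(s, bundle.voxel_size_mm, scale=1), axis=0)
        for s in resampled.streamlines
    ]


def density_map(bundle: TrajectoryBundle) -> DensityMap:
    """Voxel-wise streamline density.

    The count at a voxel is the number of distinct streamlines with at
    least one (resampled) point rounding into it; a streamline crossing
    a voxel several times still counts once.
    """
    per_track = _streamline_voxel_sets(bundle)
    allv = np.vstack(per_track)
    lo = allv.min(axis=0)
    hi = allv.max(axis=0)
    counts = np.zeros(tuple(hi - lo + 1), dtype=np.int32)
    for vox in per_track:
        idx = vox - lo
        counts[idx[:, 0], idx[:, 1], idx[:, 2]] += 1
    return DensityMap(counts=counts, origin=lo, voxel_size_mm=bundle.voxel_size_mm)


def tip_prune(
    bundle: TrajectoryBundle,
    iterations: int = 20,
    low_density_threshold: int = 1,
    keep_last: bool = False,
) -> TrajectoryBundle:
    """Iteratively remove streamlines passing through low-density voxels.

    Each iteration recomputes the density map and drops every streamline
    that touches at least one voxel with count <= ``low_density_threshold``.
    Stops early when an iteration removes nothing.  If an iteration would
    remove all remaining streamlines, raises :class:`BundleEmptiedError`
    unless ``keep_last`` is set, in which case the bundle as of the
    previous iteration is returned with a warning.

    The output streamline set is always a subset of the input.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    current = bundle
    indices = np.arange(bundle.n_streamlines)
    for it in range(1, iterations + 1):
        per_track = _streamline_voxel_sets(current)
        dmap = density_map(current)
        touches_low = np.array(
            [bool(np.any(dmap.count_at(vox) <= low_density_threshold)) for vox in per_track]
        )
        if not touches_low.any():
            break
        if touches_low.all():
            if keep_last:
                warnings.warn(
                    f"pruning iteration {it} would empty the bundle; "
                    f"returning the result of iteration {it - 1}",
                    stacklevel=2,
                )
                break
            raise BundleEmptiedError(it)
        keep = ~touches_low
        indices = indices[keep]
        current = current.subset(keep)
    return TrajectoryBundle(
        [bundle.streamlines[i] for i in indices],
        voxel_size_mm=bundle.voxel_size_mm,
        label=bundle.label,
        ground_truth=bundle.ground_truth,
    )
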