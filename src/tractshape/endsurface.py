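"""End-surface extraction and metrics.

Streamline coordinates may be stored in either direction (antegrade or
retrograde), so the two termination points of a streamline cannot be
grouped into "end surface 1" and "end surface 2" by storage order alone.
A constrained two-cluster iteration resolves this: it is k-means with
k = 2, modified so that the two endpoints of the same streamline always
land in different clusters.  Starting from the storage order (all first
points in cluster 1, all last points in cluster 2), each pass recomputes
the cluster means and, per streamline, keeps or swaps its endpoint pair
according to which pairing has the smaller total distance to the means.
Iteration stops when no endpoint changes cluster.

The clustered endpoints are then rounded onto the refined voxel grid
(same scale-2 convention as bundle voxelization) and deduplicated into
two voxel sets E1/E2; E1 is the cluster with the larger mean coordinate
along the axis of largest inter-mean separation.

End-surface metrics model each surface as a disk: area is voxel count
times squared spacing; the radius estimate exploits the fact that for a
uniform distribution over a disk of radius r the mean distance to the
centre is 2r/3, so radius = 1.5 * (mean voxel distance to the surface
centroid); irregularity = pi * radius^2 / area equals 1 for an ideal
disk and grows with protrusion, intrusion or fragmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .streamline_io import TrajectoryBundle
from .voxelize import VoxelSet, connected_components, voxelize_bundle, voxelize_points

__all__ = [
    "EndSurfacePair",
    "TrunkResult",
    "cluster_endpoints",
    "end_surface_area",
    "end_surface_radius",
    "end_surface_irregularity",
    "trunk",
]


@dataclass
class EndSurfacePair:
    """The two voxelized end surfaces with their assignment provenance.

    ``first_in_e1[i]`` is True when streamline ``i``'s first point
    belongs to the E1 cluster.  ``endpoint_vox_e1``/``_e2`` hold each
    streamline's endpoint voxel coordinate on the refined grid, used for
    trunk ROI membership.
    """

    e1: VoxelSet
    e2: VoxelSet
    first_in_e1: np.ndarray  # (n,) bool
    endpoint_vox_e1: np.ndarray  # (n, 3) int
    endpoint_vox_e2: np.ndarray  # (n, 3) int
    separation_axis: str  # "x" | "y" | "z"
    converged: bool = True
    n_iterations: int = 0


@dataclass
class TrunkResult:
    """Core sub-bundle whose endpoints lie in the main end-surface regions."""

    trunk_indices: np.ndarray  # indices into the source bundle
    trunk_volume_mm3: float


def cluster_endpoints(
    bundle: TrajectoryBundle, max_iter: int = 100, scale: int = 2
) -> EndSurfacePair:
    """Partition streamline endpoints into two end surfaces.

    Runs the constrained two-cluster iteration in mm space, then
    voxelizes the converged clusters.  Non-convergence within
    ``max_iter`` passes returns the current state with
    ``converged=False`` and a warning.
    """
    first = np.array([s[0] for s in bundle.streamlines])
    last = np.array([s[-1] for s in bundle.streamlines])
    n = len(first)

    # True: (first -> cluster1, last -> cluster2); False: swapped
    keep = np.ones(n, dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        c1 = np.where(keep[:, None], first, last)
        c2 = np.where(keep[:, None], last, first)
        m1 = c1.mean(axis=0)
        m2 = c2.mean(axis=0)
        d_first_1 = np.linalg.norm(first - m1, axis=1)
        d_first_2 = np.linalg.norm(first - m2, axis=1)
        d_last_1 = np.linalg.norm(last - m1, axis=1)
        d_last_2 = np.linalg.norm(last - m2, axis=1)
        cost_keep = d_first_1 + d_last_2
        cost_swap = d_last_1 + d_first_2
        # strict inequality: ties keep the current assignment (stability)
        new_keep = np.where(
            cost_keep < cost_swap, True, np.where(cost_swap < cost_keep, False, keep)
        )
        if np.array_equal(new_keep, keep):
            converged = True
            break
        keep = new_keep
    if not converged:
        warnings.warn(
            f"endpoint clustering did not converge in {max_iter} iterations", stacklevel=2
        )

    cluster1 = np.where(keep[:, None], first, last)
    cluster2 = np.where(keep[:, None], last, first)
    vox1 = voxelize_points(cluster1, bundle.voxel_size_mm, scale)
    vox2 = voxelize_points(cluster2, bundle.voxel_size_mm, scale)

    m1 = cluster1.mean(axis=0)
    m2 = cluster2.mean(axis=0)
    gaps = np.abs(m1 - m2)
    # axis of largest inter-mean separation; ties favour z, then y, then x
    axis = int(np.argmax(gaps[::-1]))  # argmax over (z, y, x) picks z first on ties
    axis = 2 - axis
    axis_name = "xyz"[axis]

    if m1[axis] >= m2[axis]:
        e1_pts, e2_pts, first_in_e1 = vox1, vox2, keep
    else:
        e1_pts, e2_pts, first_in_e1 = vox2, vox1, ~keep

    e1 = VoxelSet(e1_pts, scale=scale, base_voxel_size_mm=bundle.voxel_size_mm)
    e2 = VoxelSet(e2_pts, scale=scale, base_voxel_size_mm=bundle.voxel_size_mm)
    return EndSurfacePair(
        e1=e1,
        e2=e2,
        first_in_e1=first_in_e1,
        endpoint_vox_e1=e1_pts,
        endpoint_vox_e2=e2_pts,
        separation_axis=axis_name,
        converged=converged,
        n_iterations=it,
    )


def end_surface_area(e: VoxelSet) -> float:
    """Voxel count times squared effective spacing (mm^2)."""
    return e.n_voxels * e.effective_spacing_mm**2


def end_surface_radius(e: VoxelSet) -> float:
    """Disk-model radius: 1.5 x mean voxel distance to the centroid (mm)."""
    centers = e.centers_mm()
    centroid = centers.mean(axis=0)
    mean_dist = np.linalg.norm(centers - centroid, axis=1).mean()
    return 1.5 * float(mean_dist)


def end_surface_irregularity(radius: float, area: float) -> float:
    """pi * radius^2 / area; 1 for an ideal disk."""
    if not area > 0:
        raise ValueError("end-surface irregularity is undefined for zero area")
    return float(np.pi * radius**2 / area)


def trunk(
    bundle: TrajectoryBundle,
    surfaces: EndSurfacePair,
    component_connectivity: int = 26,
    scale: int = 2,
) -> TrunkResult:
    """Isolate the main trunk and measure its volume.

    The largest connected component of each end surface serves as a
    region of interest; a streamline belongs to the trunk when its E1
    endpoint voxel lies in the E1 ROI and its E2 endpoint voxel in the
    E2 ROI.  Trunk volume is the voxelized volume of that sub-bundle.
    An empty trunk yields zero volume with a warning.
    """
    roi1 = connected_components(surfaces.e1, connectivity=component_connectivity)[0]
    roi2 = connected_components(surfaces.e2, connectivity=component_connectivity)[0]
    set1 = {tuple(c) for c in roi1.coords}
    set2 = {tuple(c) for c in roi2.coords}
    in_trunk = np.array(
        [
            tuple(v1) in set1 and tuple(v2) in set2
            for v1, v2 in zip(surfaces.endpoint_vox_e1, surfaces.endpoint_vox_e2)
        ]
    )
    idx = np.flatnonzero(in_trunk)
    if idx.size == 0:
        warnings.warn("no streamline terminates in both trunk ROIs; trunk volume is 0",
                      stacklevel=2)
        return TrunkResult(trunk_indices=idx, trunk_volume_mm3=0.0)
    sub = bundle.subset(idx)
    vox = voxelize_bundle(sub, scale=scale)
    return TrunkResult(trunk_indices=idx, trunk_volume_mm3=vox.n_voxels * vox.voxel_volume_mm3)
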