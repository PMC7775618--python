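"""Bundle-level shape descriptors.

The descriptors fall into four families:

* length metrics — length (mean per-streamline arc length), span (mean
  endpoint-to-endpoint distance), cylinder-model diameter, end-surface
  radius;
* area metrics — total surface area and the two end-surface areas,
  estimated by surface-voxel counting;
* volume metrics — total volume and trunk volume, by voxel counting;
* shape metrics — dimensionless ratios: curl = length/span (1 for a
  straight bundle), elongation = length/diameter, and irregularity =
  surface area / (pi * diameter * length), the ratio of the actual
  surface to the lateral surface of the equivalent cylinder.

Voxel-based quantities carry the refined-grid bookkeeping of
:mod:`tractshape.voxelize`; at the default scale 2 on a 1 mm grid the
effective spacing is 0.5 mm and each voxel contributes 0.125 mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .streamline_io import TrajectoryBundle
from .voxelize import VoxelSet, surface_voxels, to_binary_volume, voxelize_bundle

__all__ = [
    "ShapeProfile",
    "DESCRIPTOR_NAMES",
    "bundle_length",
    "bundle_span",
    "curl",
    "bundle_volume",
    "bundle_diameter",
    "elongation",
    "bundle_surface_area",
    "irregularity",
    "compute_profile",
    "profiles_to_dataframe",
]

#: Canonical descriptor order (15 per bundle).
DESCRIPTOR_NAMES = (
    "length_mm",
    "span_mm",
    "curl",
    "diameter_mm",
    "elongation",
    "volume_mm3",
    "trunk_volume_mm3",
    "surface_area_mm2",
    "area_e1_mm2",
    "area_e2_mm2",
    "radius_e1_mm",
    "radius_e2_mm",
    "irregularity",
    "irregularity_e1",
    "irregularity_e2",
)


@dataclass
class ShapeProfile:
    """The 15 canonical descriptors for one bundle."""

    length_mm: float
    span_mm: float
    curl: float
    diameter_mm: float
    elongation: float
    volume_mm3: float
    trunk_volume_mm3: float
    surface_area_mm2: float
    area_e1_mm2: float
    area_e2_mm2: float
    radius_e1_mm: float
    radius_e2_mm: float
    irregularity: float
    irregularity_e1: float
    irregularity_e2: float
    label: str | None = None
    n_streamlines: int = 0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def descriptors(self) -> dict:
        """Only the 15 canonical descriptor values."""
        return {k: getattr(self, k) for k in DESCRIPTOR_NAMES}


def bundle_length(bundle: TrajectoryBundle) -> float:
    """Mean streamline arc length (mm): per streamline, the sum of
    consecutive-point Euclidean distances; averaged over streamlines."""
    lengths = np.array(
        [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in bundle.streamlines]
    )
    if np.any(lengths == 0):
        warnings.warn("bundle contains zero-length streamlines", stacklevel=2)
    return float(lengths.mean())


def bundle_span(bundle: TrajectoryBundle) -> float:
    """Mean endpoint-to-endpoint Euclidean distance (mm)."""
    spans = np.array([np.linalg.norm(s[0] - s[-1]) for s in bundle.streamlines])
    return float(spans.mean())


#: Bundles with mean span below this are treated as closed loops.
CLOSED_LOOP_SPAN_MM = 0.1


def curl(length: float, span: float) -> float:
    """length / span; 1 for a straight bundle, larger for curved ones.

    Refuses near-closed loops (span below 0.1 mm) rather than emitting
    a huge or infinite value.
    """
    if span < CLOSED_LOOP_SPAN_MM:
        raise ValueError(
            f"curl is undefined for span {span:.3g} mm < {CLOSED_LOOP_SPAN_MM} mm "
            "(closed-loop bundle)"
        )
    return length / span


def bundle_volume(vox: VoxelSet) -> float:
    """Voxel count times per-voxel volume (mm^3), on the refined grid."""
    return vox.n_voxels * vox.voxel_volume_mm3


def bundle_diameter(volume: float, length: float) -> float:
    """Cylinder-model diameter: 2 * sqrt(volume / (pi * length)) (mm)."""
    if not length > 0:
        raise ValueError("diameter is undefined for zero length")
    if not volume > 0:
        raise ValueError("diameter is undefined for zero volume")
    return 2.0 * float(np.sqrt(volume / (np.pi * length)))


def elongation(length: float, diameter: float) -> float:
    """length / diameter."""
    if not diameter > 0:
        raise ValueError("elongation is undefined for zero diameter")
    return length / diameter


def bundle_surface_area(vox: VoxelSet, connectivity: int = 6) -> float:
    """Surface-voxel count times squared spacing (mm^2).

    Surface voxels are foreground voxels with at least one zero-valued
    neighbour; the count includes the end caps (the innervation regions).
    """
    surf = surface_voxels(to_binary_volume(vox), connectivity=connectivity)
    return surf.n_voxels * vox.effective_spacing_mm**2


def irregularity(surface_area: float, diameter: float, length: float) -> float:
    """surface_area / (pi * diameter * length).

    The denominator is the lateral surface of the cylinder with the
    bundle's diameter and length; a value well above 1 (+ cap
    contribution D/2L) indicates a non-compact, protruding shape.
    """
    if not (diameter > 0 and length > 0):
        raise ValueError("irregularity is undefined for zero diameter or length")
    return surface_area / (np.pi * diameter * length)


def compute_profile(
    bundle: TrajectoryBundle,
    scale: int = 2,
    surface_connectivity: int = 6,
    component_connectivity: int = 26,
    max_iter: int = 100,
) -> ShapeProfile:
    """Compute all 15 canonical descriptors for one bundle.

    Deterministic given the bundle and configuration; invariant to the
    order in which streamlines are stored and to per-streamline
    orientation flips (the endpoint clustering is constrained to put the
    two ends of every streamline in different clusters).
    """
    from .endsurface import (
        cluster_endpoints,
        end_surface_area,
        end_surface_irregularity,
        end_surface_radius,
        trunk,
    )

    length = bundle_length(bundle)
    span = bundle_span(bundle)
    c = curl(length, span)

    vox = voxelize_bundle(bundle, scale=scale)
    volume = bundle_volume(vox)
    diam = bundle_diameter(volume, length)
    elong = elongation(length, diam)
    area = bundle_surface_area(vox, connectivity=surface_connectivity)
    irr = irregularity(area, diam, length)

    pair = cluster_endpoints(bundle, max_iter=max_iter, scale=scale)
    a1 = end_surface_area(pair.e1)
    a2 = end_surface_area(pair.e2)
    r1 = end_surface_radius(pair.e1)
    r2 = end_surface_radius(pair.e2)
    i1 = end_surface_irregularity(r1, a1)
    i2 = end_surface_irregularity(r2, a2)

    trunk_res = trunk(bundle, pair, component_connectivity=component_connectivity, scale=scale)

    return ShapeProfile(
        length_mm=length,
        span_mm=span,
        curl=c,
        diameter_mm=diam,
        elongation=elong,
        volume_mm3=volume,
        trunk_volume_mm3=trunk_res.trunk_volume_mm3,
        surface_area_mm2=area,
        area_e1_mm2=a1,
        area_e2_mm2=a2,
        radius_e1_mm=r1,
        radius_e2_mm=r2,
        irregularity=irr,
        irregularity_e1=i1,
        irregularity_e2=i2,
        label=bundle.label,
        n_streamlines=bundle.n_streamlines,
    )


def profiles_to_dataframe(profiles) -> pd.DataFrame:
    """One row per bundle, 15 descriptor columns plus label/n_streamlines."""
    return pd.DataFrame([p.to_dict() for p in profiles])
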