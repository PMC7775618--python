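"""Synthetic streamline bundles with analytically known descriptors.

These generators stand in for a tractography pipeline: straight
cylindrical bundles (parallel streamlines filling a circular cross
section), circular-arc "C-shaped" tubes, paired noisy test-retest
copies, and planted stray streamlines.  Every generator is deterministic
under a fixed seed and attaches closed-form ground-truth descriptor
values computed from the generating parameters, never from the analysis
pipeline, so they can serve as independent oracles in tests.

Transverse positions within a bundle cross-section are drawn uniformly
over a disk via sqrt-radius inversion — the same uniform-disk model that
calibrates the end-surface radius estimate (mean distance to centre =
2/3 of the radius).  The default axial point spacing of 0.4 mm sits
below the 0.5 mm effective voxel spacing of the default scale-2 grid,
so generated streamlines voxelize into connected traces without further
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .streamline_io import TrajectoryBundle

__all__ = [
    "CylinderSpec",
    "ArcSpec",
    "sample_disk",
    "make_cylinder",
    "make_arc",
    "make_retest_pair",
    "add_stray_streamlines",
]

DEFAULT_POINT_SPACING_MM = 0.4


def sample_disk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """n points uniform over a disk of given radius (sqrt-radius inversion)."""
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


@dataclass
class CylinderSpec:
    """Straight cylindrical bundle: parallel streamlines along z."""

    length_mm: float = 100.0
    diameter_mm: float = 10.0
    n_streamlines: int = 500
    point_spacing_mm: float = DEFAULT_POINT_SPACING_MM
    rotation: np.ndarray | None = None  # (3, 3) rotation matrix
    translation: np.ndarray | None = None  # (3,) mm
    voxel_size_mm: float = 1.0
    seed: int = 0
    label: str = "cylinder"

    def __post_init__(self):
        if not (self.length_mm > 0 and self.diameter_mm > 0):
            raise ValueError("length and diameter must be positive")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")


@dataclass
class ArcSpec:
    """Circular-arc tube ("C-shaped" bundle) in the xy-plane."""

    radius_mm: float = 50.0
    angle_rad: float = np.pi
    tube_diameter_mm: float = 4.0
    n_streamlines: int = 200
    point_spacing_mm: float = DEFAULT_POINT_SPACING_MM
    voxel_size_mm: float = 1.0
    seed: int = 0
    label: str = "arc"

    def __post_init__(self):
        if not (0 < self.angle_rad < 2 * np.pi):
            raise ValueError("angle_rad must be in (0, 2*pi)")
        if not (self.radius_mm > 0 and self.tube_diameter_mm > 0):
            raise ValueError("radius and tube diameter must be positive")


def make_cylinder(spec: CylinderSpec | None = None, **kwargs) -> TrajectoryBundle:
    """Generate a straight cylindrical bundle with ground truth attached.

    Ground-truth descriptors for a continuous cylinder of length L and
    diameter D: length = span = L, curl = 1, elongation = L/D,
    volume = pi D^2 L / 4, surface area (lateral + two caps)
    = pi D L + pi D^2 / 2, end-surface radius = D/2, end-surface area
    = pi D^2 / 4.
    """
    spec = spec if spec is not None else CylinderSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    L, D = spec.length_mm, spec.diameter_mm
    n_pts = int(np.ceil(L / spec.point_spacing_mm)) + 1
    z = np.linspace(0.0, L, n_pts)
    xy = sample_disk(spec.n_streamlines, D / 2, rng)
    R = spec.rotation if spec.rotation is not None else np.eye(3)
    t = spec.translation if spec.translation is not None else np.zeros(3)
    streamlines = []
    for x, y in xy:
        pts = np.column_stack([np.full(n_pts, x), np.full(n_pts, y), z])
        streamlines.append(pts @ R.T + t)
    truth = {
        "length_mm": L,
        "span_mm": L,
        "curl": 1.0,
        "diameter_mm": D,
        "elongation": L / D,
        "volume_mm3": np.pi * D**2 * L / 4,
        "surface_area_mm2": np.pi * D * L + np.pi * D**2 / 2,
        "area_e1_mm2": np.pi * D**2 / 4,
        "area_e2_mm2": np.pi * D**2 / 4,
        "radius_e1_mm": D / 2,
        "radius_e2_mm": D / 2,
        "irregularity": 1.0 + D / (2 * L),
        "irregularity_e1": 1.0,
        "irregularity_e2": 1.0,
    }
    return TrajectoryBundle(
        streamlines, voxel_size_mm=spec.voxel_size_mm, label=spec.label, ground_truth=truth
    )


def make_arc(spec: ArcSpec | None = None, **kwargs) -> TrajectoryBundle:
    """Generate a circular-arc tube with ground truth attached.

    Each streamline follows an arc of radius R + dr (dr from the tube
    cross-section disk) over the same subtended angle, so the bundle
    mean length is R * angle and the mean span 2 R sin(angle/2); their
    ratio, the curl, is angle / (2 sin(angle/2)) exactly.
    """
    spec = spec if spec is not None else ArcSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    R, ang = spec.radius_mm, spec.angle_rad
    offsets = sample_disk(spec.n_streamlines, spec.tube_diameter_mm / 2, rng)
    streamlines = []
    for dr, dz in offsets:
        r_i = R + dr
        n_pts = int(np.ceil(r_i * ang / spec.point_spacing_mm)) + 1
        phi = np.linspace(-ang / 2, ang / 2, n_pts)
        streamlines.append(
            np.column_stack([r_i * np.cos(phi), r_i * np.sin(phi), np.full(n_pts, dz)])
        )
    truth = {
        "length_mm": R * ang,
        "span_mm": 2 * R * np.sin(ang / 2),
        "curl": ang / (2 * np.sin(ang / 2)),
    }
    return TrajectoryBundle(
        streamlines, voxel_size_mm=spec.voxel_size_mm, label=spec.label, ground_truth=truth
    )


def make_retest_pair(
    bundle: TrajectoryBundle,
    jitter_mm: float = 0.0,
    drop_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[TrajectoryBundle, TrajectoryBundle]:
    """Two independently perturbed copies emulating repeat scans.

    Each copy gets independent Gaussian coordinate jitter (sd
    ``jitter_mm`` per axis) and an independent random drop of
    ``drop_fraction`` of the streamlines.  With zero jitter and zero
    drop the copies are identical to the input.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    def perturb() -> TrajectoryBundle:
        n = bundle.n_streamlines
        n_keep = max(1, int(round(n * (1 - drop_fraction))))
        keep = rng.choice(n, size=n_keep, replace=False) if n_keep < n else np.arange(n)
        streamlines = []
        for i in sorted(keep):
            pts = bundle.streamlines[i]
            noise = rng.normal(0, jitter_mm, pts.shape) if jitter_mm > 0 else 0.0
            streamlines.append(pts + noise)
        return TrajectoryBundle(
            streamlines, voxel_size_mm=bundle.voxel_size_mm, label=bundle.label
        )

    return perturb(), perturb()


def add_stray_streamlines(
    bundle: TrajectoryBundle,
    n_strays: int = 5,
    offset_mm: float = 30.0,
    stray_length_mm: float = 20.0,
    seed: int = 0,
) -> TrajectoryBundle:
    """Append isolated noisy streamlines well away from the bundle core.

    Each stray is a short straight streamline whose centre sits at
    ``offset_mm`` from the bundle centroid in a random direction, with a
    random orientation.  With an offset larger than the bundle extent
    the strays share no voxels with the core, so density-based pruning
    at threshold 1 removes exactly them.  An overlapping stray
    (offset ~ 0) is not guaranteed to be removed.
    """
    if n_strays == 0:
        return bundle
    rng = np.random.default_rng(seed)
    centroid = np.vstack([s.mean(axis=0) for s in bundle.streamlines]).mean(axis=0)
    strays = []
    n_pts = int(np.ceil(stray_length_mm / DEFAULT_POINT_SPACING_MM)) + 1
    for _ in range(n_strays):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = centroid + offset_mm * direction
        orient = rng.normal(size=3)
        orient /= np.linalg.norm(orient)
        ts = np.linspace(-stray_length_mm / 2, stray_length_mm / 2, n_pts)
        strays.append(center + ts[:, None] * orient)
    return TrajectoryBundle(
        list(bundle.streamlines) + strays,
        voxel_size_mm=bundle.voxel_size_mm,
        label=bundle.label,
        ground_truth=bundle.ground_truth,
    )
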