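"""Streamline bundle I/O and resampling.

A bundle is a set of streamlines, each an ordered sequence of 3D
coordinates in scanner (world) millimetre space.  All downstream geometry
— length, span, voxelization — assumes mm coordinates, so TRK files are
converted out of their native voxel-order convention at read time (nibabel
does this when asked for the ``rasmm`` space).

The only geometric operation here is :func:`resample_max_step`, which
subdivides polyline segments so that every consecutive-point gap is
strictly smaller than a target step.  This is a prerequisite for
voxelization: with gaps below the voxel spacing, the rounded trace of a
streamline is guaranteed to be a connected voxel path.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
import pandas as pd

__all__ = [
    "TrajectoryBundle",
    "read_bundle",
    "write_bundle",
    "resample_max_step",
    "bundle_to_dataframe",
]


def _as_streamline(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be an (m, 3) array, got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("streamline must have at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    return pts


@dataclass
class TrajectoryBundle:
    """A set of streamlines sharing one source voxel grid.

    Parameters
    ----------
    streamlines : list of (m_i, 3) float arrays
        Each streamline is an ordered polyline of 3D mm coordinates with
        at least two points.
    voxel_size_mm : float
        Isotropic spacing of the source image grid, in mm.
    label : str, optional
        Bundle name (e.g. ``"AF_L"``).
    ground_truth : dict, optional
        Analytic descriptor values attached by the synthetic generators;
        ``None`` for real data.
    """

    streamlines: list = field(default_factory=list)
    voxel_size_mm: float = 1.0
    label: str | None = None
    ground_truth: dict | None = None

    def __post_init__(self):
        self.streamlines = [_as_streamline(s) for s in self.streamlines]
        if len(self.streamlines) < 1:
            raise ValueError("a bundle must contain at least one streamline")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def subset(self, indices) -> "TrajectoryBundle":
        """Bundle restricted to the given streamline indices (order kept)."""
        idx = np.atleast_1d(np.asarray(indices))
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return TrajectoryBundle(
            [self.streamlines[i] for i in idx],
            voxel_size_mm=self.voxel_size_mm,
            label=self.label,
        )


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        fmt = ext
    if fmt not in ("trk", "tck"):
        raise ValueError(f"unsupported streamline format {fmt!r}; expected 'trk' or 'tck'")
    return fmt


def read_bundle(
    path: str,
    format: str | None = None,
    voxel_size_mm: float | None = None,
    label: str | None = None,
) -> TrajectoryBundle:
    """Read a TRK or TCK file into mm-space streamlines.

    TRK voxel-order offsets and the voxel-to-world affine are applied so
    returned coordinates are scanner mm.  The voxel size is taken from the
    TRK header; TCK carries no grid metadata, so it defaults to 1 mm
    unless ``voxel_size_mm`` overrides it.  Anisotropic TRK headers are
    rejected (the shape metrics assume one isotropic spacing) unless an
    explicit override is given.
    """
    fmt = _infer_format(path, format)
    tractogram_file = nib.streamlines.load(path)
    streamlines = [np.asarray(s, dtype=float) for s in tractogram_file.streamlines]
    if not streamlines:
        raise ValueError(f"{path} contains no streamlines")

    if voxel_size_mm is None:
        if fmt == "trk":
            vs = np.asarray(tractogram_file.header["voxel_sizes"], dtype=float)
            if not np.allclose(vs, vs[0], rtol=1e-4):
                raise ValueError(
                    f"anisotropic voxel sizes {tuple(vs)} in {path}: shape metrics "
                    "assume an isotropic grid; pass voxel_size_mm to force a value"
                )
            voxel_size_mm = float(vs[0])
        else:
            voxel_size_mm = 1.0

    if label is None:
        label = os.path.splitext(os.path.basename(path))[0]
    return TrajectoryBundle(streamlines, voxel_size_mm=voxel_size_mm, label=label)


def write_bundle(bundle: TrajectoryBundle, path: str, format: str | None = None) -> None:
    """Write a bundle to TRK or TCK (mm-space coordinates, float32 storage)."""
    fmt = _infer_format(path, format)
    tractogram = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in bundle.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if fmt == "trk":
        vs = float(bundle.voxel_size_mm)
        # dimensions must contain every voxel the coordinates map into
        all_pts = np.vstack(bundle.streamlines)
        dims = np.maximum(np.ceil(all_pts.max(axis=0) / vs).astype(int) + 2, 1)
        header = {
            "voxel_sizes": (vs, vs, vs),
            "dimensions": tuple(int(d) for d in dims),
            "voxel_to_rasmm": np.diag([vs, vs, vs, 1.0]),
            "voxel_order": "RAS",
        }
        nib.streamlines.save(tractogram, path, header=header)
    else:
        nib.streamlines.save(tractogram, path)


def resample_max_step(
    bundle: TrajectoryBundle, max_step_mm: float | None = None
) -> TrajectoryBundle:
    """Subdivide segments until every consecutive-point gap is < ``max_step_mm``.

    New points are placed by linear interpolation on the existing
    segments, so the polyline geometry — in particular its arc length and
    its endpoints — is preserved exactly.  Defaults to the bundle's voxel
    size, matching the voxelization prerequisite that gaps be smaller
    than the voxel spacing.
    """
    if max_step_mm is None:
        max_step_mm = bundle.voxel_size_mm
    if not max_step_mm > 0:
        raise ValueError("max_step_mm must be positive")

    out = []
    for pts in bundle.streamlines:
        seg = np.diff(pts, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        if np.all(seglen < max_step_mm):
            out.append(pts)
            continue
        pieces = [pts[:1]]
        for i, L in enumerate(seglen):
            n_sub = max(int(np.ceil(L / max_step_mm)), 1)
            if L / n_sub >= max_step_mm:  # strict inequality required
                n_sub += 1
            frac = np.arange(1, n_sub)[:, None] / n_sub
            pieces.append(pts[i] + frac * seg[i])
            pieces.append(pts[i + 1 : i + 2])  # segment end kept bit-exact
        out.append(np.vstack(pieces))
    return TrajectoryBundle(
        out,
        voxel_size_mm=bundle.voxel_size_mm,
        label=bundle.label,
        ground_truth=bundle.ground_truth,
    )


def bundle_to_dataframe(bundle: TrajectoryBundle) -> pd.DataFrame:
    """Tidy coordinate table (streamline, point, x, y, z) for debugging/CSV."""
    frames = []
    for i, pts in enumerate(bundle.streamlines):
        frames.append(
            pd.DataFrame(
                {
                    "streamline": i,
                    "point": np.arange(len(pts)),
                    "x_mm": pts[:, 0],
                    "y_mm": pts[:, 1],
                    "z_mm": pts[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
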