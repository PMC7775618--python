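"""Atlas-based track recognition by shortest Hausdorff distance.

Each candidate streamline is compared against every trajectory in a set
of labelled reference bundles (an atlas co-registered to the candidate
space).  The symmetric Hausdorff distance between the discrete point
sets is used; the candidate inherits the label of the reference bundle
containing its nearest trajectory, and candidates whose shortest
distance exceeds a cutoff (default 16 mm) are discarded as substantial
deviations from the known anatomy.

The discrete Hausdorff distance depends on point density, so both
candidates and references are resampled to a common maximum step
(default 1 mm) before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .streamline_io import TrajectoryBundle, resample_max_step

__all__ = ["ReferenceSet", "RecognitionResult", "hausdorff_distance", "recognize"]

DEFAULT_THRESHOLD_MM = 16.0


@dataclass
class ReferenceSet:
    """Named collection of reference (atlas) bundles."""

    bundles: dict = field(default_factory=dict)  # name -> TrajectoryBundle

    def __post_init__(self):
        if not self.bundles:
            raise ValueError("reference set must contain at least one bundle")
        for name, b in self.bundles.items():
            if b.n_streamlines < 1:
                raise ValueError(f"reference bundle {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return sorted(self.bundles)


@dataclass
class RecognitionResult:
    """Per-candidate label, shortest distance, and keep flag."""

    labels: np.ndarray  # (n,) str
    shortest_distance_mm: np.ndarray  # (n,) float
    kept: np.ndarray  # (n,) bool
    threshold_mm: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "shortest_distance_mm": self.shortest_distance_mm,
                "kept": self.kept,
            }
        )


def hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two polylines' point sets (mm).

    max of the two directed distances, where the directed distance from A
    to B is the largest nearest-point distance from any point of A to B.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Hausdorff distance requires non-empty point sets")
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


def recognize(
    candidates: TrajectoryBundle,
    refs: ReferenceSet,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    resample_step_mm: float = 1.0,
) -> RecognitionResult:
    """Label candidates by their nearest reference trajectory.

    Ties between equidistant reference bundles resolve to the first name
    in sorted order, so the result does not depend on dict insertion
    order or candidate ordering.
    """
    if not threshold_mm > 0:
        raise ValueError("threshold_mm must be positive")

    cand = resample_max_step(candidates, resample_step_mm)
    ref_trees: list[tuple[str, list]] = []
    for name in refs.names:
        rb = resample_max_step(refs.bundles[name], resample_step_mm)
        ref_trees.append((name, [(np.asarray(s), cKDTree(s)) for s in rb.streamlines]))

    n = cand.n_streamlines
    labels = np.empty(n, dtype=object)
    dists = np.full(n, np.inf)
    for i, s in enumerate(cand.streamlines):
        tree_s = cKDTree(s)
        best = np.inf
        best_name = None
        for name, trajs in ref_trees:
            for pts, tree in trajs:
                d = max(tree.query(s)[0].max(), tree_s.query(pts)[0].max())
                if d < best:  # strict: first (sorted) name wins ties
                    best = d
                    best_name = name
        labels[i] = best_name
        dists[i] = best
    kept = dists <= threshold_mm
    return RecognitionResult(
        labels=labels.astype(str),
        shortest_distance_mm=dists,
        kept=kept,
        threshold_mm=threshold_mm,
    )
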