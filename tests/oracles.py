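"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in the most literal way possible (plain
Python loops, sets, BFS) and shares no code path with the package.
"""

from collections import deque

import numpy as np


def brute_hausdorff(a, b):
    """Symmetric Hausdorff distance via an exhaustive double loop."""

    def directed(p_set, q_set):
        worst = 0.0
        for p in p_set:
            best = min(float(np.sqrt(((p - q) ** 2).sum())) for q in q_set)
            worst = max(worst, best)
        return worst

    return max(directed(np.asarray(a), np.asarray(b)), directed(np.asarray(b), np.asarray(a)))


def brute_surface_count(coords, connectivity=6):
    """Count foreground voxels with >= 1 empty neighbour by direct scan."""
    occupied = {tuple(int(v) for v in c) for c in coords}
    if connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        neigh = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    count = 0
    for v in occupied:
        for d in neigh:
            if (v[0] + d[0], v[1] + d[1], v[2] + d[2]) not in occupied:
                count += 1
                break
    return count


def brute_components(coords, connectivity=26):
    """Connected components via BFS flood fill; returns list of frozensets."""
    remaining = {tuple(int(v) for v in c) for c in coords}
    if connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        neigh = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    comps = []
    while remaining:
        seed = next(iter(remaining))
        remaining.discard(seed)
        comp = {seed}
        queue = deque([seed])
        while queue:
            v = queue.popleft()
            for d in neigh:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if w in remaining:
                    remaining.discard(w)
                    comp.add(w)
                    queue.append(w)
        comps.append(frozenset(comp))
    return comps


def brute_density(voxel_sets):
    """Voxel -> number of distinct streamlines touching it.

    ``voxel_sets`` is one iterable of (i, j, k) tuples per streamline.
    """
    counts = {}
    for vs in voxel_sets:
        for v in set(vs):
            counts[v] = counts.get(v, 0) + 1
    return counts


def anova_icc11(x1, x2):
    """ICC(1,1) assembled step by step from one-way ANOVA sums of squares."""
    x1 = list(map(float, x1))
    x2 = list(map(float, x2))
    n = len(x1)
    grand = sum(x1 + x2) / (2 * n)
    ssb = 0.0
    ssw = 0.0
    for a, b in zip(x1, x2):
        m = (a + b) / 2
        ssb += 2 * (m - grand) ** 2
        ssw += (a - m) ** 2 + (b - m) ** 2
    msb = ssb / (n - 1)
    msw = ssw / n
    return (msb - msw) / (msb + msw)
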