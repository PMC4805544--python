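"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's code paths (and scipy's
clustering): plain-Python threshold sweeps and a Lance-Williams
complete-linkage merger with explicit O(n^3) bookkeeping.
"""

from __future__ import annotations

import numpy as np


def auroc_oracle(test, baseline, step: float = 0.01) -> float:
    """Brute-force ROC area: explicit threshold sweep and trapezoid sum."""
    t = [float(x) for x in test]
    b = [float(x) for x in baseline]
    mn, mx = min(t + b), max(t + b)
    if mx == mn:
        return 0.5
    tn = [(x - mn) / (mx - mn) for x in t]
    bn = [(x - mn) / (mx - mn) for x in b]
    n = round(1.0 / step)
    pts = [(0.0, 0.0)]
    for i in range(n, -1, -1):
        thr = i / n
        hit = sum(1 for x in tn if x > thr) / len(tn)
        fa = sum(1 for x in bn if x > thr) / len(bn)
        pts.append((fa, hit))
    pts.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def complete_linkage_oracle(points: np.ndarray, k: int) -> list[frozenset]:
    """Complete-linkage partition as a set of frozensets of row indices.

    Maintains an explicit inter-cluster distance matrix with the
    complete-linkage (maximum) update rule; merges the closest pair at
    each step, breaking exact ties by lowest pair indices.
    """
    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(clusters) > k:
        keys = sorted(clusters)
        best, pair = np.inf, None
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                i, j = keys[a], keys[b]
                dij = dist[(min(i, j), max(i, j))]
                if dij < best:
                    best, pair = dij, (i, j)
        i, j = pair
        clusters[i] |= clusters.pop(j)
        for m in clusters:
            if m == i:
                continue
            a, b = (min(i, m), max(i, m)), (min(j, m), max(j, m))
            dist[a] = max(dist[a], dist.pop(b))
    return [frozenset(c) for c in clusters.values()]


def partition_of(labels) -> set[frozenset]:
    out: dict[int, set[int]] = {}
    for i, c in enumerate(labels):
        out.setdefault(int(c), set()).add(i)
    return {frozenset(v) for v in out.values()}


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation from raw sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x ** 2).sum() - sx ** 2) * np.sqrt(n * (y ** 2).sum() - sy ** 2)
    return float(num / den)


def paired_t_oracle(diffs) -> float:
    """Textbook one-sample t on paired differences."""
    d = np.asarray(diffs, float)
    n = len(d)
    return float(d.mean() / (d.std(ddof=1) / np.sqrt(n)))
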