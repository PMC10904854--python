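"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities with naive textbook algorithms
(double loops, ECDF sweeps, greedy agglomeration, dense grids) so that the
package's vectorized/library-backed implementations are checked against a
separate route.
"""

from __future__ import annotations

import math

import numpy as np


def textbook_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def ecdf_ks(a, b):
    """Sup distance between empirical CDFs by sweeping every sample point."""
    points = sorted(set(list(a) + list(b)))
    na, nb = len(a), len(b)
    best = 0.0
    for t in points:
        fa = sum(1 for v in a if v <= t) / na
        fb = sum(1 for v in b if v <= t) / nb
        best = max(best, abs(fa - fb))
    return best


def sliding_mean(values, window):
    """Centered truncated sliding mean, scalar implementation."""
    n = len(values)
    half = window // 2
    out = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out


def histogram_counts(values, edges):
    counts = [0] * (len(edges) - 1)
    for v in values:
        for k in range(len(edges) - 1):
            last = k == len(edges) - 2
            if edges[k] <= v < edges[k + 1] or (last and v == edges[-1]):
                counts[k] += 1
                break
    return counts


def rg_direct(coords, masses):
    m = sum(masses)
    cx = sum(mi * c[0] for mi, c in zip(masses, coords)) / m
    cy = sum(mi * c[1] for mi, c in zip(masses, coords)) / m
    cz = sum(mi * c[2] for mi, c in zip(masses, coords)) / m
    s = sum(
        mi * ((c[0] - cx) ** 2 + (c[1] - cy) ** 2 + (c[2] - cz) ** 2)
        for mi, c in zip(masses, coords)
    )
    return math.sqrt(s / m)


def lj_coulomb_double_loop(coords, eps, rmin_half, charges, ke=332.0637):
    e_vdw = e_ele = 0.0
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            r = math.dist(coords[i], coords[j])
            e_ij = math.sqrt(eps[i] * eps[j])
            rmin = rmin_half[i] + rmin_half[j]
            e_vdw += e_ij * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
            e_ele += ke * charges[i] * charges[j] / r
    return e_vdw, e_ele


def jaccard_distance(a, b):
    union = sum(1 for x, y in zip(a, b) if x or y)
    if union == 0:
        return 0.0
    inter = sum(1 for x, y in zip(a, b) if x and y)
    return 1.0 - inter / union


def naive_average_linkage(fingerprints, threshold):
    """O(n^3) agglomerative average-linkage clustering under Jaccard distance.

    Merges the closest cluster pair while the average pairwise distance stays
    below the threshold; ties broken by lowest member indices.  Returns the
    partition as a set of frozensets of frame indices.
    """
    n = len(fingerprints)
    dist = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = jaccard_distance(fingerprints[i], fingerprints[j])
            dist[i][j] = dist[j][i] = d
    clusters = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = sum(dist[i][j] for i in clusters[a] for j in clusters[b]) / (
                    len(clusters[a]) * len(clusters[b])
                )
                key = (avg, min(clusters[a]), min(clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (avg, _, _), a, b = best
        if avg > threshold:
            break
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return {frozenset(c) for c in clusters}


def grid_union_area(centers_xy, radii, resolution=0.02):
    """Dense-grid union area of disks (oracle for the Monte-Carlo estimator)."""
    centers = np.asarray(centers_xy, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lo = (centers - radii[:, None]).min(axis=0) - resolution
    hi = (centers + radii[:, None]).max(axis=0) + resolution
    xs = np.arange(lo[0], hi[0], resolution)
    ys = np.arange(lo[1], hi[1], resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    inside = (d2 <= radii**2).any(axis=1)
    return inside.sum() * resolution**2


def two_disk_mean_union(r_disk, separation, n_quad=20000):
    """Orientation-averaged union area of two equal disks from a 3D dumbbell.

    Under a uniform random rotation the projected center separation is
    L*sqrt(1-z^2) with z uniform on (-1, 1); the union area is 2A minus the
    lens overlap, integrated in closed form over z.
    """
    area = math.pi * r_disk**2

    def lens(d):
        if d >= 2 * r_disk:
            return 0.0
        if d <= 0:
            return area
        h = d / (2 * r_disk)
        return 2 * r_disk**2 * math.acos(h) - 0.5 * d * math.sqrt(4 * r_disk**2 - d**2)

    zs = (np.arange(n_quad) + 0.5) / n_quad  # z uniform on (0,1) by symmetry
    total = sum(lens(separation * math.sqrt(1 - z * z)) for z in zs) / n_quad
    return 2 * area - total
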