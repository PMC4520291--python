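"""Independent brute-force oracles used to check the library's fast paths.

Everything here is deliberately naive (triple loops, O(n^2) searches,
explicit agglomeration) and shares no code with the implementation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((a[i] - ma) * (b[i] - mb) for i in range(n))
    da = sum((a[i] - ma) ** 2 for i in range(n))
    db = sum((b[i] - mb) ** 2 for i in range(n))
    return num / math.sqrt(da * db)


def naive_mi(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Equal-width binning over each array's own range, MI in bits."""
    x = x.ravel()
    y = y.ravel()

    def assign(v):
        lo, hi = v.min(), v.max()
        if lo == hi:
            hi = lo + 1.0
        idx = np.minimum(((v - lo) / (hi - lo) * bins).astype(int), bins - 1)
        return idx

    ix, iy = assign(x), assign(y)
    joint = np.zeros((bins, bins))
    for a, b in zip(ix, iy):
        joint[a, b] += 1
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log2(joint[a, b] / (px[a] * py[b]))
    return mi


def naive_chamfer(x_points: np.ndarray, y_points: np.ndarray) -> float:
    total = 0.0
    for x in x_points:
        best = math.inf
        for y in y_points:
            d = math.dist(x, y)
            if d < best:
                best = d
        total += best
    return total / len(x_points)


def _pad_symmetric(grid: np.ndarray) -> np.ndarray:
    return np.pad(grid, 1, mode="symmetric")


def brute_sobel_magnitude(grid: np.ndarray) -> np.ndarray:
    """3D Sobel gradient magnitude via explicit 3x3x3 kernel loops."""
    smooth = np.array([1.0, 2.0, 1.0])
    diff = np.array([1.0, 0.0, -1.0])
    kernels = []
    for axis in range(3):
        parts = [smooth, smooth, smooth]
        parts[axis] = diff
        k = np.einsum("i,j,k->ijk", parts[0], parts[1], parts[2])
        kernels.append(k)
    padded = _pad_symmetric(np.asarray(grid, dtype=float))
    nz, ny, nx = grid.shape
    out = np.zeros_like(np.asarray(grid, dtype=float))
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                sq = 0.0
                for k in kernels:
                    acc = 0.0
                    for dz in range(3):
                        for dy in range(3):
                            for dx in range(3):
                                acc += k[dz, dy, dx] * padded[z + dz, y + dy, x + dx]
                    sq += acc * acc
                out[z, y, x] = math.sqrt(sq)
    return out


def brute_laplacian(grid: np.ndarray) -> np.ndarray:
    """6-neighbour Laplacian with reflective (symmetric) padding."""
    padded = _pad_symmetric(np.asarray(grid, dtype=float))
    nz, ny, nx = grid.shape
    out = np.zeros((nz, ny, nx))
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                c = padded[z + 1, y + 1, x + 1]
                out[z, y, x] = (
                    padded[z, y + 1, x + 1]
                    + padded[z + 2, y + 1, x + 1]
                    + padded[z + 1, y, x + 1]
                    + padded[z + 1, y + 2, x + 1]
                    + padded[z + 1, y + 1, x]
                    + padded[z + 1, y + 1, x + 2]
                    - 6.0 * c
                )
    return out


def brute_surface_scan(grid: np.ndarray, threshold: float) -> set[tuple[int, int, int]]:
    """Voxels >= threshold with a 6-face neighbour below threshold
    (out-of-grid counts as below)."""
    nz, ny, nx = grid.shape
    points = set()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if grid[z, y, x] < threshold:
                    continue
                for dz, dy, dx in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
                ):
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                        points.add((z, y, x))
                        break
                    if grid[zz, yy, xx] < threshold:
                        points.add((z, y, x))
                        break
    return points


def naive_complete_linkage_labels(matrix: np.ndarray, cutoff: float) -> list[int]:
    """Flat clusters by naive agglomeration with complete linkage.

    Merge the pair of clusters with the smallest complete-linkage distance
    while that distance is <= cutoff; tie-break on lowest member index.
    """
    n = matrix.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        best_d = math.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(matrix[a, b] for a in clusters[i] for b in clusters[j])
                if d < best_d - 1e-12:
                    best_d = d
                    best = (i, j)
        if best is None or best_d > cutoff:
            break
        i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = [0] * n
    for cid, members in enumerate(clusters, start=1):
        for m in members:
            labels[m] = cid
    return labels


def same_partition(labels_a, labels_b) -> bool:
    """True when two labelings induce the same partition (up to relabelling)."""
    groups_a = {}
    groups_b = {}
    for i, (a, b) in enumerate(zip(labels_a, labels_b)):
        groups_a.setdefault(a, set()).add(i)
        groups_b.setdefault(b, set()).add(i)
    return set(map(frozenset, groups_a.values())) == set(map(frozenset, groups_b.values()))


def naive_borda_totals(rank_matrix: np.ndarray) -> np.ndarray:
    """Total Borda points (N - r per score) for a fits x scores rank matrix."""
    n_fits, n_scores = rank_matrix.shape
    totals = np.zeros(n_fits)
    for j in range(n_fits):
        for s in range(n_scores):
            totals[j] += n_fits - rank_matrix[j, s]
    return totals
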