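"""Brute-force reference implementations used to validate the raster operators.

Each oracle follows the mathematical definition directly (per-pixel loops,
set unions, exhaustive scans, BFS) and is kept independent of the library's
vectorized implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def dense_gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Dense 2-D convolution with an explicitly sampled, truncated,
    renormalized Gaussian kernel; symmetric (reflect) boundary."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k1 = np.exp(-(x**2) / (2.0 * sigma**2))
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    padded = np.pad(np.asarray(image, dtype=np.float64), radius, mode="symmetric")
    h, w = image.shape
    out = np.empty((h, w), dtype=np.float64)
    for r in range(h):
        for c in range(w):
            window = padded[r:r + 2 * radius + 1, c:c + 2 * radius + 1]
            out[r, c] = float((window * kernel).sum())
    return out


def exhaustive_otsu(image: np.ndarray, n_bins: int = 256):
    """Exhaustive between-class-variance scan over all histogram cut-points.

    Returns (best_cut_upper_edge, foreground_mask) with the smallest
    maximizing cut and the right-open binning convention of np.histogram.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    counts, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_t = -1.0, None
    for t in range(n_bins - 1):
        n0 = counts[: t + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / n0
        mu1 = (counts[t + 1:] * centers[t + 1:]).sum() / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    if best_t is None:
        return None, np.zeros(image.shape, dtype=bool)
    cut = edges[best_t + 1]
    return cut, image >= cut


def median3x3(arr: np.ndarray) -> np.ndarray:
    """Per-pixel 3x3 median with edge replication."""
    a = np.asarray(arr, dtype=np.float64)
    padded = np.pad(a, 1, mode="edge")
    h, w = a.shape
    out = np.empty_like(a)
    for r in range(h):
        for c in range(w):
            out[r, c] = np.median(padded[r:r + 3, c:c + 3])
    if arr.dtype == bool:
        return out > 0.5
    return out.astype(arr.dtype)


def set_dilate(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Union of 3x3-translated copies of every foreground pixel, clipped."""
    m = np.asarray(mask, dtype=bool)
    for _ in range(iterations):
        out = np.zeros_like(m)
        h, w = m.shape
        for r, c in zip(*np.nonzero(m)):
            out[max(0, r - 1):min(h, r + 2), max(0, c - 1):min(w, c + 2)] = True
        m = out
    return m


def set_erode(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Pixels whose full 3x3 neighborhood is foreground (outside = background)."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    for _ in range(iterations):
        out = np.zeros_like(m)
        for r in range(h):
            for c in range(w):
                if not m[r, c]:
                    continue
                ok = True
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < h and 0 <= cc < w and m[rr, cc]):
                            ok = False
                if ok:
                    out[r, c] = True
        m = out
    return m


def bfs_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Foreground plus background components unreachable from the border
    by a 4-connected BFS."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    reached = np.zeros_like(m)
    queue: deque = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not m[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not m[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not m[rr, cc] and not reached[rr, cc]:
                reached[rr, cc] = True
                queue.append((rr, cc))
    return m | ~reached


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def union_find_label(mask: np.ndarray, connectivity: int = 8,
                     min_area: float = 0.0, max_area: float = np.inf) -> np.ndarray:
    """Connected-component labeling by union-find, with explicit size
    filtering and scan-order relabeling."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    uf = _UnionFind(h * w)
    if connectivity == 8:
        neigh = ((-1, -1), (-1, 0), (-1, 1), (0, -1))
    else:
        neigh = ((-1, 0), (0, -1))
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            for dr, dc in neigh:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and m[rr, cc]:
                    uf.union(rr * w + cc, r * w + c)
    roots = {}
    labels = np.zeros((h, w), dtype=np.int32)
    for r in range(h):
        for c in range(w):
            if m[r, c]:
                root = uf.find(r * w + c)
                if root not in roots:
                    roots[root] = len(roots) + 1
                labels[r, c] = roots[root]
    # size filter + relabel in scan order of each survivor's first pixel
    areas = np.bincount(labels.ravel())
    out = np.zeros_like(labels)
    next_label = 0
    remap = {}
    for r in range(h):
        for c in range(w):
            lab = labels[r, c]
            if lab == 0 or areas[lab] < min_area or areas[lab] > max_area:
                continue
            if lab not in remap:
                next_label += 1
                remap[lab] = next_label
            out[r, c] = remap[lab]
    return out


def pooled_t_test(a, b):
    """Closed-form two-sided unpaired Student t test with pooled variance."""
    import math

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.special import betainc

    df = na + nb - 2
    x = df / (df + t * t)
    p = betainc(df / 2.0, 0.5, x)
    return t, p
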