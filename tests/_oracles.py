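"""Independent brute-force oracles used by the test suite.

Every routine here is deliberately naive (exhaustive search, BFS flood fill)
and shares no code with the package implementations it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_clusters(mask: np.ndarray, connectivity: int = 26) -> list[int]:
    """Cluster sizes of a boolean volume by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offs.append((dz, dy, dx))
    seen = np.zeros_like(mask)
    sizes = []
    nz, ny, nx = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        q = deque([start])
        seen[start] = True
        size = 0
        while q:
            z, y, x = q.popleft()
            size += 1
            for dz, dy, dx in offs:
                p = (z + dz, y + dy, x + dx)
                if 0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx \
                        and mask[p] and not seen[p]:
                    seen[p] = True
                    q.append(p)
        sizes.append(size)
    return sizes


def gamma_bruteforce(mask: np.ndarray, connectivity: int = 26) -> float:
    sizes = np.array(bfs_clusters(mask, connectivity), dtype=np.float64)
    return float((sizes**2).sum() / sizes.sum() ** 2)


def nearest_distance_bruteforce(target: np.ndarray) -> np.ndarray:
    """Per-voxel minimum Euclidean distance to any True voxel of ``target``."""
    pts = np.argwhere(target).astype(np.float64)
    nz, ny, nx = target.shape
    grid = np.stack(np.mgrid[0:nz, 0:ny, 0:nx], axis=-1).reshape(-1, 3).astype(np.float64)
    out = np.empty(len(grid))
    for i in range(0, len(grid), 2048):
        chunk = grid[i:i + 2048]
        d2 = ((chunk[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        out[i:i + 2048] = d2.min(axis=1)
    return np.sqrt(out).reshape(target.shape)


def local_thickness_bruteforce(pore: np.ndarray) -> np.ndarray:
    """Maximum-inscribed-sphere diameter per pore voxel, exhaustively.

    Candidate centres are all pore voxels; a centre c carries a ball of
    radius R(c) = min distance to any solid voxel (or domain edge treated as
    open).  A voxel x is covered by c when |x − c| < R(c); its diameter is
    2·max R − 1 (an isolated voxel gets 1).
    """
    pore = np.asarray(pore, dtype=bool)
    solid_pts = np.argwhere(~pore).astype(np.float64)
    pore_pts = np.argwhere(pore).astype(np.float64)
    if len(solid_pts) == 0:
        raise ValueError("oracle needs some solid")
    radius2 = np.empty(len(pore_pts))
    for i in range(0, len(pore_pts), 1024):
        d2 = ((pore_pts[i:i + 1024, None, :] - solid_pts[None, :, :]) ** 2).sum(axis=2)
        radius2[i:i + 1024] = d2.min(axis=1)  # R^2 per candidate centre
    out = np.zeros(pore.shape)
    best = np.empty(len(pore_pts))
    for i in range(0, len(pore_pts), 1024):
        cross = ((pore_pts[i:i + 1024, None, :] - pore_pts[None, :, :]) ** 2).sum(axis=2)
        # strictly inside the ball; squared-integer comparison avoids float
        # ties at |x - c| == R
        covered = cross < radius2[None, :] - 1e-9
        best[i:i + 1024] = np.sqrt(np.where(covered, radius2[None, :], 0.0).max(axis=1))
    for (z, y, x), b in zip(pore_pts.astype(int), best):
        out[z, y, x] = 2.0 * b - 1.0
    return out


def two_threshold_otsu_bruteforce(values: np.ndarray, nbins: int = 256):
    """Exhaustive two-threshold search maximizing between-class variance."""
    hist, edges = np.histogram(values, bins=nbins)
    mids = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    best, arg = -1.0, None
    for i in range(1, nbins - 1):
        for j in range(i + 1, nbins):
            var = 0.0
            ok = True
            for sl in (slice(0, i), slice(i, j), slice(j, nbins)):
                w = p[sl].sum()
                if w <= 0:
                    ok = False
                    break
                mu = (p[sl] * mids[sl]).sum() / w
                var += w * mu**2
            if ok and var > best:
                best, arg = var, (mids[i - 1], mids[j - 1])
    return arg
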