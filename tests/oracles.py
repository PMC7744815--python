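"""Independent brute-force oracles for texture matrices and statistics.

Everything here is written as plain enumeration (voxel-pair loops, run
walks, BFS flood fill, neighbor scans) so that it shares no code path with
the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(grid: np.ndarray, c) -> bool:
    return all(0 <= c[i] < grid.shape[i] for i in range(3)) and grid[c] > 0


def glcm_bruteforce(grid: np.ndarray, ng: int) -> np.ndarray:
    """Count every ordered voxel pair at distance 1 over the 13 directions
    and both orders."""
    counts = np.zeros((ng, ng), dtype=int)
    for c in itertools.product(*(range(s) for s in grid.shape)):
        if grid[c] == 0:
            continue
        for d in OFFSETS_13:
            o = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
            if _in(grid, o):
                counts[grid[c] - 1, grid[o] - 1] += 1
                counts[grid[o] - 1, grid[c] - 1] += 1
    return counts


def glrlm_bruteforce(grid: np.ndarray, ng: int, directions=None) -> np.ndarray:
    """Walk every maximal run per direction."""
    directions = directions or OFFSETS_13
    runs: list[tuple[int, int]] = []
    for d in directions:
        for c in itertools.product(*(range(s) for s in grid.shape)):
            if grid[c] == 0:
                continue
            prev = (c[0] - d[0], c[1] - d[1], c[2] - d[2])
            if _in(grid, prev) and grid[prev] == grid[c]:
                continue  # not a run start
            length = 1
            cur = c
            while True:
                nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if _in(grid, nxt) and grid[nxt] == grid[c]:
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((grid[c], length))
    rmax = max(l for _, l in runs)
    counts = np.zeros((ng, rmax), dtype=int)
    for lvl, length in runs:
        counts[lvl - 1, length - 1] += 1
    return counts


def glszm_bruteforce(grid: np.ndarray, ng: int) -> np.ndarray:
    """BFS flood fill of 26-connected equal-level zones."""
    seen = np.zeros(grid.shape, dtype=bool)
    zones: list[tuple[int, int]] = []
    for c in itertools.product(*(range(s) for s in grid.shape)):
        if grid[c] == 0 or seen[c]:
            continue
        level = grid[c]
        stack = [c]
        seen[c] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                o = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if _in(grid, o) and not seen[o] and grid[o] == level:
                    seen[o] = True
                    stack.append(o)
        zones.append((level, size))
    zmax = max(s for _, s in zones)
    counts = np.zeros((ng, zmax), dtype=int)
    for lvl, size in zones:
        counts[lvl - 1, size - 1] += 1
    return counts


def ngtdm_bruteforce(grid: np.ndarray, ng: int):
    """Neighbor-mean scan: s_i, n_i over voxels with >= 1 in-region neighbor."""
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=int)
    for c in itertools.product(*(range(s_) for s_ in grid.shape)):
        if grid[c] == 0:
            continue
        nbrs = [
            grid[c[0] + d[0], c[1] + d[1], c[2] + d[2]]
            for d in NEIGHBORS_26
            if _in(grid, (c[0] + d[0], c[1] + d[1], c[2] + d[2]))
        ]
        if not nbrs:
            continue
        s[grid[c] - 1] += abs(grid[c] - float(np.mean(nbrs)))
        n[grid[c] - 1] += 1
    return s, n, int(n.sum())


def fisher_score_direct(x: np.ndarray, y: np.ndarray) -> float:
    """F = [n1(mu1-mu)^2 + n2(mu2-mu)^2] / [n1 s1^2 + n2 s2^2], population s."""
    x0, x1 = x[y == 0], x[y == 1]
    mu = x.mean()
    num = len(x0) * (x0.mean() - mu) ** 2 + len(x1) * (x1.mean() - mu) ** 2
    den = len(x0) * x0.var() + len(x1) * x1.var()
    return float("inf") if den == 0 and num > 0 else num / den


def auc_pair_counting(scores, outcomes) -> float:
    """AUC by exhaustive case/control pair comparison, ties 1/2."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes)
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def partial_corr_inverse(x, y, covs) -> float:
    """Partial correlation from the inverse of the joint correlation matrix."""
    m = np.column_stack([x, y, covs])
    prec = np.linalg.inv(np.corrcoef(m, rowvar=False))
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


def ols_residuals_normal_equations(Y, X) -> np.ndarray:
    """Residuals via explicit normal equations (X'X) b = X'Y."""
    D = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(D.T @ D, D.T @ Y)
    return Y - D @ beta
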