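"""3D texture features of an atlas region: 43 values per region.

The set is 3 global intensity moments + 9 gray-level co-occurrence (GLCM)
+ 13 gray-level run-length (GLRLM) + 13 gray-level size-zone (GLSZM)
+ 5 neighborhood gray-tone difference (NGTDM) features, computed on the raw
region voxels (global moments) or on a quantized copy (matrix families).

Conventions, fixed and documented here:

* Quantization: uniform min-max binning into ``Ng`` levels (default 32);
  a constant region maps to level 1 everywhere.
* GLCM and GLRLM pool all 13 unique 3D directions at distance 1 into a
  single merged matrix (GLCM additionally symmetrized over pair order).
* GLSZM zones are 26-connected components of equal level.
* NGTDM uses the 26-neighborhood restricted to in-region voxels.
* Degenerate cases (single voxel, zero denominators) emit a configured
  sentinel value and a log record instead of aborting cohort extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

# The 13 canonical non-opposite unit offsets in 3D (one per direction pair).
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS) == 13

GLOBAL_NAMES = ("variance", "skewness", "kurtosis")
GLCM_NAMES = (
    "energy", "contrast", "entropy", "homogeneity", "correlation",
    "sum_average", "variance", "dissimilarity", "autocorrelation",
)
GLRLM_NAMES = (
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV",
)
GLSZM_NAMES = (
    "SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
    "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV",
)
NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

#: (family, name) pairs in the fixed output order; length 43.
TEXTURE_FEATURE_ORDER: tuple[tuple[str, str], ...] = (
    tuple(("global", n) for n in GLOBAL_NAMES)
    + tuple(("GLCM", n) for n in GLCM_NAMES)
    + tuple(("GLRLM", n) for n in GLRLM_NAMES)
    + tuple(("GLSZM", n) for n in GLSZM_NAMES)
    + tuple(("NGTDM", n) for n in NGTDM_NAMES)
)
N_TEXTURE_FEATURES = len(TEXTURE_FEATURE_ORDER)
assert N_TEXTURE_FEATURES == 43


@dataclass(frozen=True)
class TextureConfig:
    Ng: int = 32
    quantization: str = "uniform_minmax"  # or "equal_probability"
    sentinel: float = 0.0            # value emitted for undefined features
    coarseness_sentinel: float = 1e6  # NGTDM coarseness when s-sum is zero

    def __post_init__(self) -> None:
        if self.Ng < 2:
            raise ValueError("Ng must be >= 2")
        if self.quantization not in ("uniform_minmax", "equal_probability"):
            raise ValueError(f"unknown quantization {self.quantization!r}")


@dataclass
class QuantizedROI:
    """Quantized region voxels: integer levels in 1..Ng plus coordinates."""

    levels: np.ndarray  # (N,) int
    coords: np.ndarray  # (N, 3) int, 0-based
    Ng: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.levels.size < 1 or self.levels.size != len(self.coords):
            raise ValueError("levels and coords must be nonempty and matched")
        if self.levels.min() < 1 or self.levels.max() > self.Ng:
            raise ValueError("levels must lie in 1..Ng")

    @property
    def n_voxels(self) -> int:
        return int(self.levels.size)

    def grid(self) -> np.ndarray:
        """Dense bounding-box array, level values inside the ROI, 0 outside."""
        lo = self.coords.min(axis=0)
        shape = self.coords.max(axis=0) - lo + 1
        g = np.zeros(tuple(shape), dtype=np.int64)
        c = self.coords - lo
        g[c[:, 0], c[:, 1], c[:, 2]] = self.levels
        return g


def quantize(intensities, coords, config: TextureConfig) -> QuantizedROI:
    """Quantize raw region intensities to integer gray levels.

    uniform_minmax: ``level = 1 + floor(Ng * (x - min) / (max - min))``
    clamped to ``Ng``; a constant region maps entirely to level 1.
    equal_probability: quantile binning into Ng (approximately) equally
    populated levels.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 1:
        raise ValueError("empty region")
    lo, hi = x.min(), x.max()
    if hi == lo:
        levels = np.ones(x.shape, dtype=np.int64)
    elif config.quantization == "uniform_minmax":
        levels = 1 + np.floor(config.Ng * (x - lo) / (hi - lo)).astype(np.int64)
        np.clip(levels, 1, config.Ng, out=levels)
    else:  # equal_probability
        edges = np.quantile(x, np.linspace(0, 1, config.Ng + 1)[1:-1])
        levels = 1 + np.searchsorted(edges, x, side="left").astype(np.int64)
    return QuantizedROI(levels=levels, coords=np.asarray(coords), Ng=config.Ng)


# ---------------------------------------------------------------------------
# Global (first-order) moments on raw intensities
# ---------------------------------------------------------------------------

def global_features(intensities, config: TextureConfig = TextureConfig()) -> dict[str, float]:
    """Population variance, skewness, and (Pearson, non-excess) kurtosis."""
    x = np.asarray(intensities, dtype=float)
    out: dict[str, float] = {}
    if x.size >= 2:
        out["variance"] = float(np.var(x))
    else:
        log.debug("global variance undefined for %d voxel(s); sentinel", x.size)
        out["variance"] = config.sentinel
    if x.size >= 3 and np.var(x) > 0:
        mu = x.mean()
        m2 = np.mean((x - mu) ** 2)
        out["skewness"] = float(np.mean((x - mu) ** 3) / m2 ** 1.5)
        out["kurtosis"] = float(np.mean((x - mu) ** 4) / m2 ** 2)
    else:
        if x.size >= 3:  # constant region: symmetric, flat
            out["skewness"] = config.sentinel
            out["kurtosis"] = config.sentinel
        else:
            log.debug("skewness/kurtosis undefined for %d voxel(s); sentinel", x.size)
            out["skewness"] = config.sentinel
            out["kurtosis"] = config.sentinel
    return out


# ---------------------------------------------------------------------------
# Matrix constructions
# ---------------------------------------------------------------------------

def _padded_grid(q: QuantizedROI) -> np.ndarray:
    g = q.grid()
    return np.pad(g, 1)


def glcm_matrix(q: QuantizedROI) -> np.ndarray:
    """Symmetric co-occurrence counts pooled over the 13 directions.

    Entry (i, j) counts ordered voxel pairs at distance 1 with levels
    i+1 and j+1; both orders are accumulated, so the matrix is symmetric.
    """
    P = _padded_grid(q)
    c = q.coords - q.coords.min(axis=0) + 1
    counts = np.zeros((q.Ng, q.Ng), dtype=np.int64)
    a = P[c[:, 0], c[:, 1], c[:, 2]]
    for d in DIRECTIONS:
        b = P[c[:, 0] + d[0], c[:, 1] + d[1], c[:, 2] + d[2]]
        m = b > 0
        np.add.at(counts, (a[m] - 1, b[m] - 1), 1)
    return counts + counts.T


def glrlm_matrix(q: QuantizedROI, directions=DIRECTIONS) -> np.ndarray:
    """Run-length counts: maximal same-level runs per direction, pooled.

    Row i, column j-1: number of runs of level i+1 and length j.  Each voxel
    belongs to exactly one run per direction, so
    ``sum_ij counts[i, j] * (j+1) = len(directions) * n_voxels``.
    """
    P = _padded_grid(q)
    c = q.coords - q.coords.min(axis=0) + 1
    lv = P[c[:, 0], c[:, 1], c[:, 2]]
    run_levels: list[np.ndarray] = []
    run_lengths: list[np.ndarray] = []
    for d in directions:
        d = np.asarray(d)
        prev = P[tuple((c - d).T)]
        start = prev != lv  # includes prev == 0 (outside ROI)
        cur = c[start]
        levels = lv[start]
        length = np.ones(len(cur), dtype=np.int64)
        while len(cur):
            nxt = cur + d
            nxt_lv = P[tuple(nxt.T)]
            cont = nxt_lv == levels
            done = ~cont
            if done.any():
                run_levels.append(levels[done])
                run_lengths.append(length[done])
            cur = nxt[cont]
            levels = levels[cont]
            length = length[cont] + 1
    all_levels = np.concatenate(run_levels)
    all_lengths = np.concatenate(run_lengths)
    rmax = int(all_lengths.max())
    counts = np.zeros((q.Ng, rmax), dtype=np.int64)
    np.add.at(counts, (all_levels - 1, all_lengths - 1), 1)
    return counts


_STRUCT26 = np.ones((3, 3, 3), dtype=int)


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Size-zone counts: 26-connected components of equal level.

    Row i, column j-1: number of zones of level i+1 and size j.  Zones
    partition the region: ``sum_ij counts[i, j] * (j+1) = n_voxels``.
    """
    g = q.grid()
    present = np.unique(q.levels)
    sizes_per_level: dict[int, np.ndarray] = {}
    zmax = 1
    for lvl in present:
        lab, n = ndimage.label(g == lvl, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level[int(lvl)] = sizes
        if n:
            zmax = max(zmax, int(sizes.max()))
    counts = np.zeros((q.Ng, zmax), dtype=np.int64)
    for lvl, sizes in sizes_per_level.items():
        np.add.at(counts, (lvl - 1, sizes - 1), 1)
    return counts


def ngtdm_arrays(q: QuantizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """NGTDM building blocks.

    Returns ``(s, n, n_valid)`` where ``s[i]`` sums, over region voxels of
    level i+1 that have at least one in-region 26-neighbor, the absolute
    difference between the voxel level and the mean level of its in-region
    neighbors; ``n[i]`` counts those voxels.
    """
    g = q.grid()
    mask = g > 0
    kernel = _STRUCT26.copy()
    kernel[1, 1, 1] = 0
    nbr_count = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    nbr_sum = ndimage.correlate(g.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nbr_count > 0.5)
    s = np.zeros(q.Ng)
    n = np.zeros(q.Ng, dtype=np.int64)
    if valid.any():
        lv = g[valid]
        mean_nbr = nbr_sum[valid] / nbr_count[valid]
        diff = np.abs(lv - mean_nbr)
        np.add.at(s, lv - 1, diff)
        np.add.at(n, lv - 1, 1)
    return s, n, int(valid.sum())


# ---------------------------------------------------------------------------
# Feature formulas
# ---------------------------------------------------------------------------

def compute_glcm_features(q: QuantizedROI, config: TextureConfig = TextureConfig()) -> dict[str, float]:
    counts = glcm_matrix(q)
    total = counts.sum()
    if total == 0:  # single-voxel region: no pairs at distance 1
        log.debug("GLCM undefined (no voxel pairs); sentinels")
        return {n: config.sentinel for n in GLCM_NAMES}
    p = counts / total
    i = np.arange(1, q.Ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    nz = p > 0
    out = {
        "energy": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "sum_average": float(((ii + jj) * p).sum()),
        "variance": float((((ii - mu) ** 2) * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "autocorrelation": float((ii * jj * p).sum()),
    }
    if sigma2 > 0:
        out["correlation"] = float((((ii - mu) * (jj - mu) * p).sum()) / sigma2)
    else:
        log.debug("GLCM correlation undefined (zero marginal variance); sentinel")
        out["correlation"] = config.sentinel
    return {n: out[n] for n in GLCM_NAMES}


def _rl_style_features(p: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    """Shared run-length / size-zone formulas on a normalized (Ng x M) matrix.

    ``names`` supplies the family-specific spelling (SRE vs SZE etc.) in the
    canonical order used by GLRLM_NAMES / GLSZM_NAMES (RP/ZP excluded —
    computed by the callers, whose normalizations differ).
    """
    Ng, M = p.shape
    i = np.arange(1, Ng + 1)[:, None].astype(float)
    j = np.arange(1, M + 1)[None, :].astype(float)
    pg = p.sum(axis=1)  # gray-level marginal
    pr = p.sum(axis=0)  # length/size marginal
    mu_i = float((np.arange(1, Ng + 1) * pg).sum())
    mu_j = float((np.arange(1, M + 1) * pr).sum())
    return {
        names[0]: float((p / j**2).sum()),          # short emphasis
        names[1]: float((p * j**2).sum()),          # long/large emphasis
        names[2]: float((pg**2).sum()),             # gray-level non-uniformity
        names[3]: float((pr**2).sum()),             # length/size non-uniformity
        names[4]: float((p / i**2).sum()),          # low gray emphasis
        names[5]: float((p * i**2).sum()),          # high gray emphasis
        names[6]: float((p / (i**2 * j**2)).sum()),
        names[7]: float((p * i**2 / j**2).sum()),
        names[8]: float((p / i**2 * j**2).sum()),
        names[9]: float((p * i**2 * j**2).sum()),
        names[10]: float((p * (i - mu_i) ** 2).sum()),  # gray-level variance
        names[11]: float((p * (j - mu_j) ** 2).sum()),  # length/size variance
    }


def compute_glrlm_features(
    q: QuantizedROI, config: TextureConfig = TextureConfig(), directions=DIRECTIONS
) -> dict[str, float]:
    counts = glrlm_matrix(q, directions)
    nr = counts.sum()
    p = counts / nr
    base = _rl_style_features(
        p, ("SRE", "LRE", "GLN", "RLN", "LGRE", "HGRE", "SRLGE", "SRHGE",
            "LRLGE", "LRHGE", "GLV", "RLV"),
    )
    # Run percentage: runs per (voxel x direction); each voxel lies in
    # exactly one run per direction.
    base["RP"] = float(nr / (q.n_voxels * len(directions)))
    return {n: base[n] for n in GLRLM_NAMES}


def compute_glszm_features(q: QuantizedROI, config: TextureConfig = TextureConfig()) -> dict[str, float]:
    counts = glszm_matrix(q)
    nz = counts.sum()
    p = counts / nz
    base = _rl_style_features(
        p, ("SZE", "LZE", "GLN", "ZSN", "LGZE", "HGZE", "SZLGE", "SZHGE",
            "LZLGE", "LZHGE", "GLV", "ZSV"),
    )
    base["ZP"] = float(nz / q.n_voxels)  # zones per voxel
    return {n: base[n] for n in GLSZM_NAMES}


def compute_ngtdm_features(q: QuantizedROI, config: TextureConfig = TextureConfig()) -> dict[str, float]:
    s, n, n_valid = ngtdm_arrays(q)
    out: dict[str, float] = {}
    if n_valid == 0:
        log.debug("NGTDM undefined (no voxel with in-region neighbors); sentinels")
        out = {name: config.sentinel for name in NGTDM_NAMES}
        out["coarseness"] = config.coarseness_sentinel
        return out
    pi = n / n_valid
    i = np.arange(1, q.Ng + 1).astype(float)
    act = pi > 0
    ngp = int(act.sum())
    ps = float((pi * s).sum())
    # coarseness
    if ps > 0:
        out["coarseness"] = float(1.0 / ps)
    else:
        log.debug("NGTDM coarseness zero-denominator; sentinel")
        out["coarseness"] = config.coarseness_sentinel
    # contrast
    if ngp > 1:
        ia, pa = i[act], pi[act]
        d2 = (ia[:, None] - ia[None, :]) ** 2
        out["contrast"] = float(
            (pa[:, None] * pa[None, :] * d2).sum() / (ngp * (ngp - 1)) * (s.sum() / n_valid)
        )
    else:
        out["contrast"] = 0.0
    # busyness
    ia, pa, sa = i[act], pi[act], s[act]
    denom = np.abs(ia[:, None] * pa[:, None] - ia[None, :] * pa[None, :]).sum()
    if denom > 0:
        out["busyness"] = float(ps / denom)
    else:
        log.debug("NGTDM busyness zero-denominator; sentinel")
        out["busyness"] = config.sentinel
    # complexity
    psum = pa[:, None] + pa[None, :]
    num = np.abs(ia[:, None] - ia[None, :]) * (
        pa[:, None] * sa[:, None] + pa[None, :] * sa[None, :]
    )
    out["complexity"] = float((num / psum).sum() / n_valid)
    # strength
    if s.sum() > 0:
        out["strength"] = float(
            ((pa[:, None] + pa[None, :]) * (ia[:, None] - ia[None, :]) ** 2).sum() / s.sum()
        )
    else:
        log.debug("NGTDM strength zero-denominator; sentinel")
        out["strength"] = config.sentinel
    return {name: out[name] for name in NGTDM_NAMES}


# ---------------------------------------------------------------------------
# Per-region assembly
# ---------------------------------------------------------------------------

def texture_feature_values(intensities, coords, config: TextureConfig = TextureConfig()) -> dict[tuple[str, str], float]:
    """All 43 texture features of one region, keyed by (family, name)."""
    q = quantize(intensities, coords, config)
    parts = {
        "global": global_features(intensities, config),
        "GLCM": compute_glcm_features(q, config),
        "GLRLM": compute_glrlm_features(q, config),
        "GLSZM": compute_glszm_features(q, config),
        "NGTDM": compute_ngtdm_features(q, config),
    }
    out = {(fam, name): parts[fam][name] for fam, name in TEXTURE_FEATURE_ORDER}
    assert len(out) == N_TEXTURE_FEATURES
    return out


def roi_feature_vector(vol, parc, label: int, config: TextureConfig = TextureConfig()) -> dict[tuple[str, str], float]:
    """43 texture features of one atlas region of a volume."""
    from .io import region_voxels

    intensities, coords = region_voxels(vol, parc, label)
    return texture_feature_values(intensities, coords, config)
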