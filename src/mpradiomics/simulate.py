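"""Synthetic cohorts emulating the study's data structure at every stage.

Two fidelity tiers:

* **image tier** — small 3D Gaussian-field volumes plus Voronoi-style
  atlases, exercising the extraction stack end to end (default 48^3 grids);
* **feature tier** — a subjects x features table drawn directly from a
  block-correlated Gaussian with planted group effects, exercising
  selection, classification, correlation and survival stages at full
  cohort scale in seconds.

Cohort-emulating defaults use the scale of a typical preclinical-AD cohort:
age about 66 +/- 6 years, education 12 +/- 3 years, amyloid SUVR around the
1.09-1.23 band with the conventional 1.18 positivity cutoff.  Every
generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import FeatureKey, FeatureMatrix, Parcellation, SubjectRecord, VoxelVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectSpec:
    """What to plant and how strongly.

    ``effect_size_d`` is the standardized mean (or variance-scale)
    difference between cases and controls; ``feature_noise_corr`` is the
    within-block correlation of the noise features (exercising the 0.8
    decorrelation rule); ``suvr_link`` is the target correlation between the
    planted-feature combination and the generated SUVR score.
    """

    n_cases: int = 90
    n_controls: int = 90
    n_planted: int = 3
    effect_size_d: float = 1.5
    signal_family: str = "shift"   # "shift" | "variance" (image tier)
    signal_regions: tuple[int, ...] = (1, 2, 3)
    feature_noise_corr: float = 0.5
    block_size: int = 10
    suvr_link: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size_d < 0:
            raise ValueError("effect_size_d must be >= 0")
        if not 0 <= self.feature_noise_corr < 1:
            raise ValueError("feature_noise_corr must be in [0, 1)")
        if min(self.n_cases, self.n_controls) < 2:
            raise ValueError("need >= 2 subjects per arm")
        if self.signal_family not in ("shift", "variance"):
            raise ValueError(f"unknown signal_family {self.signal_family!r}")


# ---------------------------------------------------------------------------
# Image tier
# ---------------------------------------------------------------------------

def synth_atlas(
    n_regions: int,
    shape: tuple[int, int, int] = (48, 48, 48),
    seed: int = 0,
    kind: str = "cortical_atlas",
    min_voxels: int = 8,
    margin_fraction: float = 0.08,
) -> Parcellation:
    """Voronoi-style parcellation of an ellipsoidal foreground.

    Region labels 1..n_regions are nearest-centroid cells around seeded
    centroids; a background shell (label 0) is retained around the
    ellipsoid.  Cells of the Euclidean Voronoi diagram are convex, hence
    connected after voxelization.
    """
    shape = tuple(shape)
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    center = (np.array(shape) - 1) / 2
    semi = (1 - margin_fraction) * np.array(shape) / 2
    inside = (((grid - center) / semi) ** 2).sum(axis=1) <= 1.0
    fg = grid[inside]
    if n_regions > len(fg):
        raise ValueError(f"{n_regions} regions exceed {len(fg)} foreground voxels")
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        centroids = fg[rng.choice(len(fg), size=n_regions, replace=False)]
        assign = cKDTree(centroids).query(fg)[1]
        sizes = np.bincount(assign, minlength=n_regions)
        if sizes.min() >= min_voxels:
            break
    else:
        raise ValueError(
            f"could not honour the minimum region size of {min_voxels} voxels"
        )
    labels = np.zeros(shape, dtype=np.int64)
    coords = fg.astype(int)
    labels[coords[:, 0], coords[:, 1], coords[:, 2]] = assign + 1
    prefix = "region" if kind == "cortical_atlas" else "tract"
    names = {i + 1: f"{prefix}_{i + 1:03d}" for i in range(n_regions)}
    return Parcellation(labels=labels, names=names, kind=kind)


def _gaussian_field(shape, rng, sigma: float = 1.0) -> np.ndarray:
    """Spatially correlated unit-scale Gaussian field (smoothed white noise)."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma)
    return sm / sm.std()


def synth_subject_volumes(
    parc: Parcellation,
    tract_parc: Parcellation,
    group: int,
    spec: EffectSpec,
    subject_seed: int,
) -> dict:
    """One subject's modality volumes with the planted texture effect.

    Region-wise mean offsets are fixed by ``spec.seed`` (shared across
    subjects); the subject's fluctuation field comes from ``subject_seed``.
    Cases (group = 1) receive the perturbation in ``spec.signal_regions``:
    a variance multiplier ``1 + d/2`` for the "variance" family, or a mean
    shift of ``d`` fluctuation-SDs for "shift".
    """
    atlas_rng = np.random.default_rng(spec.seed)
    region_means = {
        lab: 100.0 + 10.0 * atlas_rng.standard_normal() for lab in parc.region_labels
    }
    tract_base = {
        m: {
            lab: mu
            for lab, mu in zip(
                tract_parc.region_labels,
                base + spread * atlas_rng.random(len(tract_parc.region_labels)),
            )
        }
        for m, (base, spread) in {
            "diffusion_FA": (0.2, 0.6),
            "diffusion_MD": (0.4, 0.8),
            "diffusion_AD": (0.8, 0.8),
            "diffusion_RD": (0.3, 0.6),
        }.items()
    }
    rng = np.random.default_rng(subject_seed)
    out: dict = {}
    for modality in ("structural", "functional"):
        field3d = 5.0 * _gaussian_field(parc.labels.shape, rng)
        vol = np.zeros(parc.labels.shape)
        for lab in parc.region_labels:
            mask = parc.labels == lab
            fluct = field3d[mask]
            if group == 1 and modality == "structural" and lab in spec.signal_regions:
                if spec.signal_family == "variance":
                    fluct = fluct * (1.0 + spec.effect_size_d / 2.0)
                else:
                    fluct = fluct + spec.effect_size_d * fluct.std()
            vol[mask] = region_means[lab] + fluct
        out[modality] = VoxelVolume(vol, (2.0, 2.0, 2.0), modality)
    diffusion = {}
    for modality, means in tract_base.items():
        vol = np.zeros(tract_parc.labels.shape)
        noise = 0.05 * rng.standard_normal(tract_parc.labels.shape)
        for lab in tract_parc.region_labels:
            mask = tract_parc.labels == lab
            vol[mask] = means[lab] + noise[mask]
        diffusion[modality] = VoxelVolume(vol, (2.0, 2.0, 2.0), modality)
    out["diffusion"] = diffusion
    return out


# ---------------------------------------------------------------------------
# Feature tier
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    features: FeatureMatrix
    labels: np.ndarray
    records: list[SubjectRecord]
    planted_keys: list[FeatureKey]


def _feature_keys(n_features: int) -> list[FeatureKey]:
    return [
        FeatureKey("structural", f"synth_{i:05d}", "1", "global", "variance")
        for i in range(n_features)
    ]


def synth_feature_cohort(n_features: int, spec: EffectSpec) -> SyntheticCohort:
    """Feature-tier cohort: block-correlated noise plus planted group shifts.

    The first column of the first ``n_planted`` blocks carries the planted
    effect: cases are shifted by ``effect_size_d`` (features have unit SD,
    so d is Cohen's d).  Planted columns are drawn independently of their
    block so the decorrelation step cannot swap them for a noise sibling.
    SUVR is generated so that its correlation with the standardized
    planted-feature mean is ``suvr_link``.
    """
    if n_features < spec.n_planted:
        raise ValueError("n_features must cover the planted count")
    n = spec.n_cases + spec.n_controls
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(n, dtype=int)
    labels[: spec.n_cases] = 1
    rho = spec.feature_noise_corr
    b = spec.block_size
    n_blocks = int(np.ceil(n_features / b))
    factors = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, n_features))
    block_of = np.arange(n_features) // b
    values = np.sqrt(rho) * factors[:, block_of] + np.sqrt(1 - rho) * eps
    if spec.n_planted * b <= n_features:
        planted_cols = [i * b for i in range(spec.n_planted)]  # distinct blocks
    else:
        planted_cols = list(range(spec.n_planted))
    for c in planted_cols:
        values[:, c] = rng.standard_normal(n)
        values[labels == 1, c] += spec.effect_size_d
    keys = _feature_keys(n_features)
    fm = FeatureMatrix([f"S{i:04d}" for i in range(n)], keys, values)

    age = rng.normal(66.0, 6.0, n)
    sex = rng.integers(0, 2, n)
    education = np.clip(rng.normal(12.0, 3.0, n), 0, None)
    moca = np.clip(rng.normal(26.0, 3.0, n), 0, 30)
    if planted_cols:
        planted_mean = values[:, planted_cols].mean(axis=1)
        z = (planted_mean - planted_mean.mean()) / planted_mean.std()
    else:
        z = np.zeros(n)
    r = spec.suvr_link if planted_cols else 0.0
    suvr = 1.15 + 0.06 * (r * z + np.sqrt(max(0.0, 1 - r**2)) * rng.standard_normal(n))
    records = [
        SubjectRecord(
            id=fm.subjects[i], group=int(labels[i]), age=float(age[i]),
            sex=int(sex[i]), education=float(education[i]), moca=float(moca[i]),
            apoe4=int(rng.integers(0, 2)), suvr=float(suvr[i]),
        )
        for i in range(n)
    ]
    return SyntheticCohort(
        features=fm, labels=labels, records=records,
        planted_keys=[keys[c] for c in planted_cols],
    )


# ---------------------------------------------------------------------------
# Longitudinal tier
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLongitudinal:
    baseline: FeatureMatrix
    followup: FeatureMatrix
    times: np.ndarray
    events: np.ndarray
    drifted_key: FeatureKey


def synth_longitudinal(
    n_subjects: int,
    drift: float,
    hazard_model: dict | None = None,
    seed: int = 0,
    n_features: int = 3,
    followup_noise_sd: float = 0.3,
) -> SyntheticLongitudinal:
    """Baseline/follow-up features plus conversion times.

    Follow-up = baseline + drift (in baseline-SD units) + noise for the
    designated first feature; other features drift-free.  Conversion times
    are exponential; the hazard model is either
    ``{"type": "loglinear", "beta": b, "baseline_hazard": lam}`` (log-hazard
    linear in the designated feature's standardized baseline level) or
    ``{"type": "group_hr", "hr": h, "baseline_hazard": lam}`` (the
    below-median group's hazard is h times the above-median group's).
    ``censor_time`` in the model censors conversions beyond that horizon.
    """
    if n_subjects < 4:
        raise ValueError("need >= 4 subjects")
    hazard_model = hazard_model or {"type": "loglinear", "beta": 0.0, "baseline_hazard": 1 / 48.0}
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n_subjects, n_features))
    follow = base + followup_noise_sd * rng.standard_normal((n_subjects, n_features))
    follow[:, 0] += drift
    keys = _feature_keys(n_features)
    ids = [f"L{i:04d}" for i in range(n_subjects)]
    z = (base[:, 0] - base[:, 0].mean()) / base[:, 0].std()
    lam0 = hazard_model.get("baseline_hazard", 1 / 48.0)
    if hazard_model["type"] == "loglinear":
        lam = lam0 * np.exp(hazard_model.get("beta", 0.0) * z)
    elif hazard_model["type"] == "group_hr":
        low = base[:, 0] <= np.median(base[:, 0])
        lam = np.where(low, lam0 * hazard_model["hr"], lam0)
    else:
        raise ValueError(f"unknown hazard model {hazard_model['type']!r}")
    times = rng.exponential(1.0 / lam)
    events = np.ones(n_subjects, dtype=int)
    censor = hazard_model.get("censor_time")
    if censor is not None:
        events = (times <= censor).astype(int)
        times = np.minimum(times, censor)
    times = np.maximum(times, 1e-6)
    return SyntheticLongitudinal(
        baseline=FeatureMatrix(ids, keys, base),
        followup=FeatureMatrix(ids, keys, follow),
        times=times,
        events=events,
        drifted_key=keys[0],
    )
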