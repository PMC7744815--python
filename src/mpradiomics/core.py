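"""Core data model for atlas-based multiparametric-MRI radiomics.

Every stage of the pipeline passes these containers around:

* :class:`VoxelVolume` — one 3D scalar image (a gray-matter map, a temporal
  summary of a resting-state series, or a diffusion scalar map).
* :class:`Parcellation` — an integer-labelled atlas defining the regions of
  interest (116 cortical/subcortical regions) or white-matter tracts (50).
* :class:`FeatureKey` — the canonical identity of one radiomic feature:
  which modality, which region, which wavelet band-pass ratio, which texture
  family, and which named statistic.
* :class:`FeatureMatrix` — the subjects x features table all selection and
  classification stages operate on.
* :class:`SubjectRecord` — group label, covariates and longitudinal outcome
  for one participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

MODALITIES = (
    "structural",
    "functional",
    "diffusion_FA",
    "diffusion_MD",
    "diffusion_AD",
    "diffusion_RD",
)

FAMILIES = ("global", "GLCM", "GLRLM", "GLSZM", "NGTDM", "tract_scalar")

#: Wavelet band-pass weight ratios, ascending.  "1" is the unfiltered image.
RATIOS = ("1/2", "2/3", "1", "3/2", "2")

DIFFUSION_MODALITIES = tuple(m for m in MODALITIES if m.startswith("diffusion"))


def _ratio_value(r: str) -> Fraction:
    return Fraction(r)


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar image with isotropic-or-not voxel size and a modality tag."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    modality: str

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {data.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size components must be > 0, got {self.voxel_size}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        n_bad = int(np.size(data) - np.isfinite(data).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class Parcellation:
    """Integer-labelled volume (0 = background) plus a label -> name map.

    ``kind`` distinguishes the cortical atlas (116 regions, AAL-style) from
    the white-matter tract atlas (50 tracts).
    """

    labels: np.ndarray
    names: Mapping[int, str]
    kind: str  # "cortical_atlas" | "tract_atlas"

    CORTICAL_REGIONS = 116
    TRACT_REGIONS = 50

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("parcellation labels must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        present = set(int(v) for v in np.unique(labels)) - {0}
        missing = sorted(present - set(self.names))
        if missing:
            raise ValueError(f"labels present in volume but absent from names: {missing}")
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("duplicate region names in parcellation")
        if self.kind not in ("cortical_atlas", "tract_atlas"):
            raise ValueError(f"unknown parcellation kind {self.kind!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "names", dict(self.names))

    @property
    def region_labels(self) -> list[int]:
        """Sorted nonzero labels."""
        return sorted(self.names)

    def name_of(self, label: int) -> str:
        return self.names[label]


@dataclass(frozen=True)
class FeatureKey:
    """Canonical feature identity.

    The canonical string form ``modality|region|R|family|name`` round-trips
    losslessly and defines the tie-break and column order used everywhere.
    """

    modality: str
    region: str
    ratio_R: str
    family: str
    name: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.ratio_R not in RATIOS:
            raise ValueError(f"ratio_R must be one of {RATIOS}, got {self.ratio_R!r}")
        if self.family == "tract_scalar":
            if self.modality not in DIFFUSION_MODALITIES or self.ratio_R != "1":
                raise ValueError("tract_scalar features require a diffusion modality and R=1")
        for part in (self.modality, self.region, self.ratio_R, self.family, self.name):
            if "|" in part:
                raise ValueError(f"'|' not allowed inside key component {part!r}")

    def canonical(self) -> str:
        return "|".join((self.modality, self.region, self.ratio_R, self.family, self.name))

    @classmethod
    def parse(cls, text: str) -> "FeatureKey":
        parts = text.split("|")
        if len(parts) != 5:
            raise ValueError(f"malformed feature key {text!r}")
        return cls(*parts)

    def sort_tuple(self) -> tuple:
        """Canonical ordering: modality block, region-major, ratio ascending,
        family, then name."""
        return (
            MODALITIES.index(self.modality),
            self.region,
            _ratio_value(self.ratio_R),
            FAMILIES.index(self.family),
            self.name,
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: group label, covariates, amyloid burden, outcome.

    ``suvr`` is the mean cortical standardized uptake value ratio from
    amyloid PET (consumed as a scalar; the conventional positivity cutoff
    is 1.18).  ``conversion_months`` / ``event`` describe time to cognitive
    conversion or censoring.
    """

    id: str
    group: int
    age: float
    sex: int
    education: float
    moca: float | None = None
    apoe4: int | None = None
    suvr: float | None = None
    conversion_months: float | None = None
    event: int | None = None

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise ValueError(f"group must be 0/1, got {self.group!r}")
        if self.conversion_months is not None and not self.conversion_months > 0:
            raise ValueError("conversion_months must be > 0 when present")
        if self.event and self.conversion_months is None:
            raise ValueError("event requires conversion_months")


class FeatureMatrix:
    """Subjects x features table with canonical :class:`FeatureKey` columns."""

    def __init__(self, subjects: Sequence[str], keys: Sequence[FeatureKey], values) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2D (subjects x features)")
        if values.shape != (len(subjects), len(keys)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(subjects)} subjects x {len(keys)} keys"
            )
        canon = [k.canonical() for k in keys]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate canonical feature keys")
        if len(set(subjects)) != len(subjects):
            raise ValueError("duplicate subject ids")
        self.subjects = list(subjects)
        self.keys = list(keys)
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def key_index(self) -> dict[str, int]:
        return {k.canonical(): i for i, k in enumerate(self.keys)}

    def column(self, key: FeatureKey) -> np.ndarray:
        return self.values[:, self.key_index()[key.canonical()]]

    def subset(self, keys: Iterable[FeatureKey]) -> "FeatureMatrix":
        idx = self.key_index()
        cols = [idx[k.canonical()] for k in keys]
        return FeatureMatrix(self.subjects, [self.keys[c] for c in cols], self.values[:, cols])

    def rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        return FeatureMatrix(
            [self.subjects[i] for i in indices], self.keys, self.values[np.asarray(indices)]
        )

    def sorted_canonical(self) -> "FeatureMatrix":
        order = sorted(range(len(self.keys)), key=lambda i: self.keys[i].sort_tuple())
        return FeatureMatrix(self.subjects, [self.keys[i] for i in order], self.values[:, order])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.subjects == other.subjects
            and [k.canonical() for k in self.keys] == [k.canonical() for k in other.keys]
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureMatrix({len(self.subjects)} subjects x {len(self.keys)} features)"
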