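"""Readers and writers for the formats the pipeline touches.

Volumes and atlases travel as NIfTI (via nibabel); participant tables and
feature matrices as TSV.  Geometry beyond the voxel size is ignored: all
images are assumed spatially normalized, so extraction is purely
label-mask driven on the voxel grid (0-based indices).
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import FeatureKey, FeatureMatrix, Parcellation, SubjectRecord, VoxelVolume

log = logging.getLogger(__name__)


def load_volume(path, modality: str, summarize_4d: str | None = None) -> VoxelVolume:
    """Load a single 3D NIfTI volume.

    A 4D image (e.g. a resting-state series) is only accepted together with a
    ``summarize_4d`` directive; ``"mean"`` reduces it to the temporal mean
    volume before texture extraction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        if summarize_4d is None:
            raise ValueError(
                f"{path} is 4D; pass summarize_4d='mean' (or another reducer) to load it"
            )
        if summarize_4d == "mean":
            data = data.mean(axis=3)
        elif summarize_4d == "median":
            data = np.median(data, axis=3)
        else:
            raise ValueError(f"unknown 4D summarization {summarize_4d!r}")
    elif data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    n_bad = int(np.size(data) - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxel(s)")
    zooms = img.header.get_zooms()[:3]
    return VoxelVolume(data=data, voxel_size=tuple(float(z) for z in zooms), modality=modality)


def save_volume(vol: VoxelVolume, path) -> None:
    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), affine), str(path))


def load_parcellation(path, names_path, kind: str | None = None) -> Parcellation:
    """Load an integer-labelled atlas plus its label -> region-name table.

    ``names_path`` is a two-column TSV (label, name).  When ``kind`` is not
    given it is inferred from the declared region count: 116 regions -> the
    cortical atlas, 50 -> the tract atlas; any other count must be declared
    explicitly.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label volume contains non-integer values")
    labels = np.round(data).astype(np.int64)
    table = pd.read_csv(names_path, sep="\t", header=None, names=["label", "name"])
    names = {int(r.label): str(r.name) for r in table.itertuples()}
    if len(names) != len(table):
        raise ValueError(f"{names_path}: duplicate labels")
    present = set(int(v) for v in np.unique(labels)) - {0}
    missing = sorted(present - set(names))
    if missing:
        raise ValueError(f"labels present in volume but absent from names: {missing}")
    if kind is None:
        n = len(names)
        if n == Parcellation.CORTICAL_REGIONS:
            kind = "cortical_atlas"
        elif n == Parcellation.TRACT_REGIONS:
            kind = "tract_atlas"
        else:
            raise ValueError(
                f"cannot infer atlas kind from {n} regions "
                f"(expected {Parcellation.CORTICAL_REGIONS} or {Parcellation.TRACT_REGIONS}); "
                "pass kind= explicitly"
            )
    return Parcellation(labels=labels, names=names, kind=kind)


def save_parcellation(parc: Parcellation, path, names_path) -> None:
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int32), np.eye(4)), str(path))
    pd.DataFrame(
        {"label": list(parc.names), "name": [parc.names[k] for k in parc.names]}
    ).to_csv(names_path, sep="\t", header=False, index=False)


def region_voxels(vol: VoxelVolume, parc: Parcellation, label: int):
    """Intensities and 0-based grid coordinates of one atlas region."""
    if vol.shape != parc.labels.shape:
        raise ValueError(f"grid shape mismatch: volume {vol.shape} vs atlas {parc.labels.shape}")
    if label == 0 or label not in parc.names:
        raise ValueError(f"label {label} not present in parcellation")
    mask = parc.labels == label
    if not mask.any():
        raise ValueError(f"label {label} has no voxels in the label volume")
    coords = np.argwhere(mask)
    return vol.data[mask], coords


# ---------------------------------------------------------------------------
# Feature-matrix persistence (TSV, full decimal round-trip)
# ---------------------------------------------------------------------------

def persist_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Write a TSV: first column subject id, header = canonical key strings.

    Floats are written with ``repr`` precision so that read(write(fm)) == fm
    exactly.
    """
    canon = [k.canonical() for k in fm.keys]
    if len(set(canon)) != len(canon):
        raise ValueError("duplicate canonical feature keys")
    with open(path, "w") as fh:
        fh.write("subject\t" + "\t".join(canon) + "\n")
        for sid, row in zip(fm.subjects, fm.values):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_feature_matrix(path) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "subject":
            raise ValueError(f"{path}: malformed header (first column must be 'subject')")
        keys = [FeatureKey.parse(h) for h in header[1:]]
        if len({k.canonical() for k in keys}) != len(keys):
            raise ValueError(f"{path}: duplicate feature keys in header")
        subjects, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}: row with {len(parts)} fields, expected {len(header)}")
            subjects.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(keys)))
    return FeatureMatrix(subjects, keys, values)


# ---------------------------------------------------------------------------
# Participant tables
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "id", "group", "age", "sex", "education", "moca", "apoe4", "suvr",
    "conversion_months", "event",
]


def write_subject_table(records: list[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in _RECORD_COLUMNS})
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, sep="\t", index=False)


def read_subject_table(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(name, cast=float):
            v = d.get(name)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else cast(v)

        records.append(
            SubjectRecord(
                id=str(d["id"]),
                group=int(d["group"]),
                age=float(d["age"]),
                sex=int(d["sex"]),
                education=float(d["education"]),
                moca=opt("moca"),
                apoe4=opt("apoe4", int),
                suvr=opt("suvr"),
                conversion_months=opt("conversion_months"),
                event=opt("event", int),
            )
        )
    return records
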