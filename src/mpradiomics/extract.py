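"""Per-subject feature extraction across modalities.

Column layout (fixed so that occurrence tallies are comparable across runs):
modality blocks in the order structural, functional, diffusion FA/MD/AD/RD;
within a block region-major (ascending atlas label); within a region the
band-pass ratio R ascending (1/2, 2/3, 1, 3/2, 2); within a ratio the 43
texture features in their fixed family/name order.

Structural: 116 regions x (43 texture + 172 wavelet) = 24,940 columns.
Functional (temporal-summary volume, no wavelet pass): 116 x 43 = 4,988.
Diffusion: 50 tracts x 4 scalar maps (tract means) = 200.
Full multimodal set: 30,128 columns.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np

from .core import FeatureKey, FeatureMatrix, Parcellation, VoxelVolume
from .io import region_voxels
from .texture import TEXTURE_FEATURE_ORDER, TextureConfig, texture_feature_values
from .wavelets import WAVELET_RATIOS, BandpassSetting, bandpass_filter

log = logging.getLogger(__name__)

#: All five ratios in ascending numeric order ("1" = unfiltered).
ALL_RATIOS = tuple(sorted(("1",) + WAVELET_RATIOS, key=Fraction))

DIFFUSION_ORDER = ("diffusion_FA", "diffusion_MD", "diffusion_AD", "diffusion_RD")


def tract_mean_features(
    maps: dict[str, VoxelVolume], parc: Parcellation
) -> dict[FeatureKey, float]:
    """Mean of each diffusion scalar map over each white-matter tract.

    ``maps`` holds the four diffusion modalities; the result enumerates
    50 tracts x 4 maps = 200 keys in canonical order (map-major).
    """
    if parc.kind != "tract_atlas":
        raise ValueError("tract means require the tract atlas")
    missing = [m for m in DIFFUSION_ORDER if m not in maps]
    if missing:
        raise ValueError(f"missing diffusion maps: {missing}")
    empty = [
        parc.names[lab]
        for lab in parc.region_labels
        if not (parc.labels == lab).any()
    ]
    if empty:
        raise ValueError(f"empty tracts (0 voxels): {empty}")
    out: dict[FeatureKey, float] = {}
    for modality in DIFFUSION_ORDER:
        vol = maps[modality]
        if vol.shape != parc.labels.shape:
            raise ValueError(
                f"{modality} map shape {vol.shape} incongruent with atlas {parc.labels.shape}"
            )
        for lab in parc.region_labels:
            intensities, _ = region_voxels(vol, parc, lab)
            key = FeatureKey(
                modality=modality, region=parc.names[lab], ratio_R="1",
                family="tract_scalar", name=modality.split("_")[1],
            )
            out[key] = float(intensities.mean())
    return out


def _region_block(
    vol: VoxelVolume,
    parc: Parcellation,
    config: TextureConfig,
    ratios: tuple[str, ...],
    basis: str = "sym8",
) -> dict[FeatureKey, float]:
    """Texture features of every region at every requested ratio.

    Each filtered volume is computed once and reused across regions.
    """
    volumes = {
        "1": vol,
        **{
            r: bandpass_filter(vol, BandpassSetting(ratio_R=r, basis=basis))
            for r in ratios
            if r != "1"
        },
    }
    region_cache = {
        lab: region_voxels(vol, parc, lab)[1] for lab in parc.region_labels
    }
    out: dict[FeatureKey, float] = {}
    for lab in parc.region_labels:
        coords = region_cache[lab]
        region = parc.names[lab]
        for r in sorted(ratios, key=Fraction):
            data = volumes[r].data
            intensities = data[coords[:, 0], coords[:, 1], coords[:, 2]]
            feats = texture_feature_values(intensities, coords, config)
            for (family, name), value in feats.items():
                out[FeatureKey(vol.modality, region, r, family, name)] = value
    return out


def modality_feature_block(
    structural: VoxelVolume | None = None,
    functional: VoxelVolume | None = None,
    diffusion: dict[str, VoxelVolume] | None = None,
    cortical_atlas: Parcellation | None = None,
    tract_atlas: Parcellation | None = None,
    config: TextureConfig = TextureConfig(),
    basis: str = "sym8",
) -> dict[FeatureKey, float]:
    """All feature columns for one subject, for whichever modalities are given."""
    out: dict[FeatureKey, float] = {}
    if structural is not None:
        if cortical_atlas is None:
            raise ValueError("structural extraction requires the cortical atlas")
        out.update(_region_block(structural, cortical_atlas, config, ALL_RATIOS, basis))
    if functional is not None:
        if cortical_atlas is None:
            raise ValueError("functional extraction requires the cortical atlas")
        out.update(_region_block(functional, cortical_atlas, config, ("1",), basis))
    if diffusion is not None:
        if tract_atlas is None:
            raise ValueError("diffusion extraction requires the tract atlas")
        out.update(tract_mean_features(diffusion, tract_atlas))
    if not out:
        raise ValueError("no modality supplied")
    return out


def assemble_feature_matrix(
    per_subject: dict[str, dict[FeatureKey, float]]
) -> FeatureMatrix:
    """Stack per-subject feature dicts into a canonical FeatureMatrix."""
    subjects = list(per_subject)
    first = per_subject[subjects[0]]
    keys = sorted(first, key=lambda k: k.sort_tuple())
    values = np.empty((len(subjects), len(keys)))
    for i, sid in enumerate(subjects):
        feats = per_subject[sid]
        if set(feats) != set(first):
            raise ValueError(f"subject {sid} has a different feature set")
        values[i] = [feats[k] for k in keys]
    return FeatureMatrix(subjects, keys, values)
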