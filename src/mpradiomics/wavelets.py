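"""Wavelet band-pass filtering of whole volumes and the 172-feature block.

A single-level 3D discrete wavelet transform splits a volume into eight
sub-bands.  The purely low-pass (LLL) and purely high-pass (HHH) sub-bands
are kept at unit weight; the six mixed band-pass sub-bands (LLH ... HHL)
are multiplied by a weight ratio R before inverse transformation.  R > 1
amplifies band-pass content, R < 1 suppresses it, and R = 1 reproduces the
input exactly (perfect reconstruction).  Texture extraction on the filtered
volume at the four ratios R in {1/2, 2/3, 3/2, 2} yields 4 x 43 = 172
wavelet features per region, complementing the 43 unfiltered ones.

The whole volume is filtered before region masking — filtering a masked
fragment would corrupt region boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pywt

from .core import VoxelVolume
from .texture import TEXTURE_FEATURE_ORDER, TextureConfig, roi_feature_vector

#: Band-pass ratios carrying wavelet features, ascending.
WAVELET_RATIOS = ("1/2", "2/3", "3/2", "2")

_PURE_BANDS = ("aaa", "ddd")  # LLL and HHH


@dataclass(frozen=True)
class BandpassSetting:
    ratio_R: str
    basis: str = "sym8"
    levels: int = 1
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        Fraction(self.ratio_R)  # must parse
        if self.levels != 1:
            raise ValueError("only single-level decomposition is supported")

    @property
    def weight(self) -> float:
        return float(Fraction(self.ratio_R))


def bandpass_filter(vol: VoxelVolume, setting: BandpassSetting) -> VoxelVolume:
    """Re-weight the six band-pass wavelet sub-bands by R and reconstruct."""
    wavelet = pywt.Wavelet(setting.basis)
    if min(vol.shape) < 2:
        raise ValueError(
            f"volume shape {vol.shape} too small for the {setting.basis} filter support"
        )
    coeffs = pywt.dwtn(vol.data, wavelet, mode=setting.mode)
    w = setting.weight
    scaled = {k: (c if k in _PURE_BANDS else w * c) for k, c in coeffs.items()}
    rec = pywt.idwtn(scaled, wavelet, mode=setting.mode)
    rec = rec[tuple(slice(0, s) for s in vol.shape)]  # crop odd-length padding
    return VoxelVolume(data=rec, voxel_size=vol.voxel_size, modality=vol.modality)


def wavelet_feature_vector(
    vol: VoxelVolume, parc, label: int, config: TextureConfig = TextureConfig(),
    basis: str = "sym8",
) -> dict[tuple[str, str, str], float]:
    """172 wavelet features of one region: (ratio, family, name) -> value.

    For each R in ascending order the whole volume is filtered, then the 43
    texture features are extracted from the region of the filtered volume.
    """
    out: dict[tuple[str, str, str], float] = {}
    for r in WAVELET_RATIOS:
        filtered = bandpass_filter(vol, BandpassSetting(ratio_R=r, basis=basis))
        feats = roi_feature_vector(filtered, parc, label, config)
        for (family, name), value in feats.items():
            out[(r, family, name)] = value
    assert len(out) == 4 * len(TEXTURE_FEATURE_ORDER)
    return out
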