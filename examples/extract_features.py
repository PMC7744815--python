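"""Extract the multimodal radiomic feature set from one synthetic subject.

Builds a 116-region cortical atlas and a 50-tract atlas on a 48^3 grid,
simulates one subject's structural / functional / diffusion volumes, and
extracts every feature column: 215 per cortical region on structural MRI
(43 texture + 4 x 43 wavelet band-pass), 43 per region on the functional
summary volume, and 4 tract means per white-matter tract.
"""

from mpradiomics import EffectSpec, modality_feature_block, synth_atlas
from mpradiomics.simulate import synth_subject_volumes

cortical = synth_atlas(116, (48, 48, 48), seed=0, kind="cortical_atlas")
tracts = synth_atlas(50, (48, 48, 48), seed=1, kind="tract_atlas")
vols = synth_subject_volumes(cortical, tracts, group=1,
                             spec=EffectSpec(seed=0, signal_regions=(1, 2)),
                             subject_seed=42)

features = modality_feature_block(
    structural=vols["structural"], functional=vols["functional"],
    diffusion=vols["diffusion"], cortical_atlas=cortical, tract_atlas=tracts,
)

counts = {}
for key in features:
    block = "diffusion" if key.modality.startswith("diffusion") else key.modality
    counts[block] = counts.get(block, 0) + 1

print("feature columns per modality block:")
for block, n in counts.items():
    print(f"  {block:11s} {n:6d}")
print(f"  {'total':11s} {len(features):6d}")
example = next(k for k in features if k.family == "GLSZM" and k.name == "LZHGE")
print(f"\nexample column  {example.canonical()} = {features[example]:.3f}")
print("(large-zone high-gray-level emphasis of one region at band-pass ratio "
      f"{example.ratio_R}; the structural block is 116 regions x 215 columns)")
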