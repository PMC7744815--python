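import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mpradiomics.core import FeatureKey, FeatureMatrix, Parcellation, VoxelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    return VoxelVolume(rng.random((8, 8, 8)) * 100, (2.0, 2.0, 2.0), "structural")


@pytest.fixture
def tiny_parcellation():
    """4x4x4 checkerboard of labels 1/2 (32 voxels each)."""
    idx = np.indices((4, 4, 4)).sum(axis=0)
    labels = np.where(idx % 2 == 0, 1, 2).astype(np.int64)
    return Parcellation(labels=labels, names={1: "even", 2: "odd"}, kind="tract_atlas")


def make_feature_matrix(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    keys = [
        FeatureKey("structural", f"{prefix}_{i:04d}", "1", "global", "variance")
        for i in range(values.shape[1])
    ]
    subjects = [f"S{i:03d}" for i in range(values.shape[0])]
    return FeatureMatrix(subjects, keys, values)


@pytest.fixture
def feature_matrix_factory():
    return make_feature_matrix
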