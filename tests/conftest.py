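import sys
from pathlib import Path

import numpy as np
import pytest
from shapely.geometry import box

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_roi():
    return box(0.0, 0.0, 5000.0, 5000.0)


@pytest.fixture
def clustered_scene():
    """A deterministic two-channel clustered scene with ground truth."""
    from smquant.simulate import ClusterSceneParams, simulate_clustered_channels

    params = ClusterSceneParams(n_clusters=30, molecules_per_cluster=30,
                                cluster_sd=25.0, background_fraction=0.1,
                                coloc_fraction=0.5, seed=42)
    return simulate_clustered_channels(params)
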