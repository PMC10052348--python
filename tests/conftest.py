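"""Shared fixtures: the standard synthetic world, curated once per session."""

import numpy as np
import pytest

from pcmscreen.curation import curate_dataset
from pcmscreen.synthetic import make_world
from pcmscreen.targets import FeatureConfig, layer_feature_matrix

GLOBAL_SEED = 12345


@pytest.fixture(scope="session")
def small_world():
    """Standard benchmark world: 12 proteins / 3 tiers, 400 compounds, 2000 records."""
    return make_world("small", seed=GLOBAL_SEED)


@pytest.fixture(scope="session")
def curated(small_world):
    records, report = curate_dataset(small_world.records, small_world.sequences)
    return records, report


@pytest.fixture(scope="session")
def signal_records(small_world, curated):
    """Curated records restricted to the signal-bearing (non-decoy) proteins."""
    records, _ = curated
    return [r for r in records if r.target_id not in small_world.decoy_proteins]


@pytest.fixture(scope="session")
def benchmark_xy(small_world, signal_records):
    """PCM design matrix for the modeling benchmark (256-bit ECFP + physchem + ACC)."""
    config = FeatureConfig(ecfp_bits=256)
    features, labels = layer_feature_matrix(signal_records, small_world.sequences, config)
    return features, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(GLOBAL_SEED)
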