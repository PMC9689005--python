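import numpy as np
import pytest

from entrostress import (
    HyperCube,
    SceneConfig,
    default_state_specs,
    generate_experiment,
    subsample_feature_dataset,
)

MASTER_SEED = 1


@pytest.fixture(scope="session")
def scene_config():
    return SceneConfig()


@pytest.fixture(scope="session")
def scenes_long(scene_config):
    """Default long-period experiment (7 key days)."""
    return generate_experiment(scene_config, default_state_specs("long"), seed=MASTER_SEED)


@pytest.fixture(scope="session")
def scenes_short(scene_config):
    return generate_experiment(scene_config, default_state_specs("short"), seed=MASTER_SEED)


@pytest.fixture(scope="session")
def table_long(scenes_long):
    """Feature table at the study's default sampling (100 samples/day)."""
    return subsample_feature_dataset(scenes_long, samples_per_day=100, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def table_long_small(scenes_long):
    """Smaller table for structural/arithmetic checks."""
    return subsample_feature_dataset(scenes_long, samples_per_day=12, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def table_short(scenes_short):
    return subsample_feature_dataset(scenes_short, samples_per_day=60, seed=MASTER_SEED)


@pytest.fixture
def tiny_cube():
    """2x2x4 cube with known channel values."""
    data = np.arange(16, dtype=float).reshape(2, 2, 4)
    return HyperCube(data, wavelengths=[450.0, 550.0, 630.0, 800.0])
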