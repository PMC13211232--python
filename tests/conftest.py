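"""Shared fixtures.

The expensive physics pools are session-scoped and shared by the
integration and acceptance tests; everything else is cheap and local.
"""

from __future__ import annotations

import pytest

from bedfall import build_world
from bedfall.episodes import EpisodeConfig
from bedfall.experiments import generate_datasets
from bedfall.labels import LabelConfig
from bedfall.sampling import SamplerConfig


@pytest.fixture(scope="session")
def world():
    return build_world()


@pytest.fixture(scope="session")
def sampler_config():
    return SamplerConfig()


@pytest.fixture(scope="session")
def episode_config():
    return EpisodeConfig()


@pytest.fixture(scope="session")
def label_config(world):
    return LabelConfig(sim_timestep=world.sim_timestep)


@pytest.fixture(scope="session")
def stratified_pool():
    """Full-protocol pose-stratified pool: 100k balanced train, 50k
    pose-balanced test — the study's reference dataset."""
    return generate_datasets(seed=11, n_train=100_000, n_test=50_000, strategy="pose_stratified")


@pytest.fixture(scope="session")
def random_train_10k():
    """Fully-random-sampling training set (10k, class-balanced)."""
    return generate_datasets(seed=11, n_train=10_000, n_test=0, strategy="fully_random")
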