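"""Shared fixtures. Heavy artifacts (trained classifiers, the 256-px
morphometry corpus) are session-scoped so unit and acceptance tests
reuse the same computations."""

import numpy as np
import pytest
from hypothesis import settings

from mousemime.pipeline import (
    morphometry_statespace,
    run_synthetic_experiment,
)
from mousemime.synthetic_faces import (
    STATES,
    SceneConfig,
    generate_dataset,
    render,
    sample_params,
    tiny_profile,
)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25, database=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_scene():
    return tiny_profile()


@pytest.fixture(scope="session")
def small_records(tiny_scene):
    """30 tiny frames (10 per state) with ground truth."""
    return generate_dataset(10, tiny_scene, seed=5)


@pytest.fixture(scope="session")
def frames256():
    """A few full-resolution frames per state for mask/morphometry tests."""
    cfg = SceneConfig()
    return [render(sample_params(st, 100 + i, cfg), cfg)
            for st in STATES for i in range(4)]


@pytest.fixture(scope="session")
def experiment():
    """One trained desk-scale classifier (300 images/state, 110
    iterations)."""
    return run_synthetic_experiment(n_per_state=300, seed=1)


@pytest.fixture(scope="session")
def three_seed_results(experiment):
    """Three independently seeded end-to-end runs for seed-averaged
    metrics."""
    return [experiment,
            run_synthetic_experiment(n_per_state=300, seed=2),
            run_synthetic_experiment(n_per_state=300, seed=3)]


@pytest.fixture(scope="session")
def morpho_corpus():
    """300 frames/state at full resolution with their ground truth."""
    return generate_dataset(300, SceneConfig(), seed=11)


@pytest.fixture(scope="session")
def morpho_analysis(morpho_corpus):
    return morphometry_statespace(morpho_corpus)
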