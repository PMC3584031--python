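"""Shared fixtures: small synthetic worlds and hand-built model bundles."""

from __future__ import annotations

import numpy as np
import pytest

from distapp.experiment_harness import build_models
from distapp.similarity_core import Modality
from distapp.synthetic_data import WorldConfig, make_world
from distapp.trial_engine import ModelBundle


def random_bundle(n_words: int, rng: np.random.Generator) -> ModelBundle:
    """A ModelBundle with arbitrary symmetric distance matrices.

    No coupling between modalities: useful for exercising trial
    mechanics without the cost of a full pipeline.
    """

    def sym(scale: float) -> np.ndarray:
        m = rng.uniform(0, scale, size=(n_words, n_words))
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        return m

    words = tuple(f"w{i}" for i in range(n_words))
    return ModelBundle(
        words=words,
        dist=sym(2.0),
        app={Modality.COLOUR: sym(1.0), Modality.TEXTON: sym(1.0)},
    )


@pytest.fixture(scope="session")
def small_world():
    """A coupled (rho = 1) world small enough for fast unit tests."""
    return make_world(
        WorldConfig(n_categories=12, images_per_category=10, rho=1.0, seed=11)
    )


@pytest.fixture(scope="session")
def small_models(small_world):
    """Trial-ready models and appearance sets for the small world."""
    rng = np.random.default_rng(11)
    models, sets = build_models(small_world, rng, n_occurrences=120)
    return models, sets
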