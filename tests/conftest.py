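"""Shared fixtures: small synthetic scenes and a session-scoped pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from psoriscan.pipeline import run_pipeline
from psoriscan.synthetic import LesionSceneParams, generate_scene


@pytest.fixture(scope="session")
def severe_scene():
    """One reproducible high-severity scene (strong erythema and scale)."""
    return generate_scene(LesionSceneParams(
        image_size=(256, 256), erythema_score=4, scale_score=3, seed=11))


@pytest.fixture(scope="session")
def healthy_scene():
    return generate_scene(LesionSceneParams(
        image_size=(256, 256), erythema_score=0, scale_score=0, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run (mode B, texture+color) shared by e2e tests.

    30 scenes of 256x256 (6 per severity group) keep the run around a
    minute while leaving >1000 dataset rows after augmentation.
    """
    out = tmp_path_factory.mktemp("pipeline")
    cfg = {
        "seed": 1,
        "out_dir": str(out),
        "simulate": {"n_per_group": 6, "image_size": [256, 256]},
        "augment": {"mode": "B"},
        "extract": {"groups": ["texture", "color"]},
        "select": {"enabled": True},
        "train_eval": {"classifiers": ["rf", "knn"], "k_folds": 5,
                       "repeats": 10},
    }
    summary = run_pipeline(cfg)
    return out, summary
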