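"""Shared fixtures: small synthetic scenes and a fitted color model."""
from __future__ import annotations

import numpy as np
import pytest

import plasmaseg as ps


@pytest.fixture(scope="session")
def small_scene():
    """A compact 5-cell scene (one 2-cell cluster) used across modules."""
    spec = ps.default_scene_spec(
        shape=(128, 128), n_single=3, cluster_sizes=(2,), n_unstained=1
    )
    img, truth = ps.generate_scene(spec, seed=7)
    return img, truth


@pytest.fixture(scope="session")
def default_scene():
    img, truth = ps.generate_scene(ps.default_scene_spec(), seed=3)
    return img, truth


@pytest.fixture(scope="session")
def fitted_model(small_scene):
    """Color model fitted on an independent training scene (same conditions)."""
    spec = ps.default_scene_spec(
        shape=(128, 128), n_single=3, cluster_sizes=(2,), n_unstained=1
    )
    img, truth = ps.generate_scene(spec, seed=99)
    return ps.fit_model_from_truth(img, truth)


@pytest.fixture(scope="session")
def scene_maps(small_scene, fitted_model):
    """Probability maps and distance images of the small scene."""
    img, _ = small_scene
    stretched = ps.contrast_stretch(img)
    stack = ps.to_channel_stack(stretched)
    cleaned = ps.remove_unstained(
        stack, stretched, bg_color=fitted_model.region_rgb_mean("background")
    )
    stack = ps.to_channel_stack(cleaned)
    weights = ps.assign_weights(ps.distance_table_from_model(fitted_model))
    pmaps = ps.probability_maps(stack, fitted_model, weights)
    dimgs = ps.distance_images(stack, fitted_model, weights)
    return pmaps, dimgs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
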