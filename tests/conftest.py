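"""Shared fixtures: desk-scale simulated scenes and a trained classifier.

Scenes use a 128 px crop at 1.8 um/px (the 200 um well then spans 111 px)
so the whole pipeline runs in seconds; the physics and processing chain are
identical to full-scale runs.
"""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import secretomap as sm

SCENE_KW = dict(
    crop_side=128,
    object_pixel_size_um=1.8,
    frame_interval_min=10.0,
    n_frames=73,
)


def make_scene_config(kind: str, seed: int = 0, **overrides) -> sm.SceneConfig:
    profile_kw = overrides.pop("profile_kw", {})
    kw = {**SCENE_KW, **overrides}
    return sm.SceneConfig(
        profile=sm.SecretionProfile(kind=kind, **profile_kw), seed=seed, **kw
    )


def analyze_scene(config: sm.SceneConfig) -> tuple[sm.AnalysisResult, sm.SceneGroundTruth]:
    """Simulate and run the pipeline with ground-truth masks and known circle."""
    pair, truth = sm.simulate_pair(config)
    masks = sm.accumulate_masks(truth.cell_masks)
    center = (config.crop_side - 1) / 2.0
    circle = sm.WellCircle((center, center), config.well_radius_px)
    result = sm.analyze_pair(
        pair, masks, config.object_pixel_size_um**2, circle=circle
    )
    return result, truth


@pytest.fixture(scope="session")
def constant_scene():
    """A default constant-rate (type I) scene, analyzed once per session."""
    config = make_scene_config("constant", seed=0)
    pair, truth = sm.simulate_pair(config)
    return config, pair, truth


@pytest.fixture(scope="session")
def constant_result(constant_scene):
    config, pair, truth = constant_scene
    masks = sm.accumulate_masks(truth.cell_masks)
    center = (config.crop_side - 1) / 2.0
    circle = sm.WellCircle((center, center), config.well_radius_px)
    result = sm.analyze_pair(pair, masks, config.object_pixel_size_um**2, circle=circle)
    return config, result, truth


@pytest.fixture(scope="session")
def trained_classifier():
    """Random forest trained on sparse labels from two simulated frames."""
    rng = np.random.default_rng(42)
    config = make_scene_config(
        "none", seed=11, crop_side=96, object_pixel_size_um=2.4, n_frames=4
    )
    pair, truth = sm.simulate_pair(config)
    feats, labels = [], []
    for t in (0, 2):
        frame = pair.sensing.stack.frames[t]
        feats.append(sm.compute_pixel_features(frame))
        lab = np.zeros(frame.shape, dtype=np.uint8)
        cell = truth.cell_masks[t]
        # sparse labels: sample some cell and some background pixels
        cell_px = np.argwhere(cell)
        bg_px = np.argwhere(~cell)
        for r, c in cell_px[rng.choice(len(cell_px), 200)]:
            lab[r, c] = sm.tracking.LABEL_CELL
        for r, c in bg_px[rng.choice(len(bg_px), 400)]:
            lab[r, c] = sm.tracking.LABEL_BACKGROUND
        labels.append(lab)
    clf = sm.train_pixel_classifier(feats, labels, n_trees=50, seed=0)
    return clf, config, pair, truth
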