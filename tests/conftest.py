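"""Shared fixtures: rendered training data and a session-wide trained model.

The trained pixel classifier is expensive (six rendered columns spanning the
four seeding densities), so it is built once per session and shared between
the segmentation quality tests and the end-to-end counting tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import scaffoldcount as sc

#: Densities (cells per 500-ul scaffold) the training images span.
TRAIN_DENSITIES = (10_000, 125_000, 250_000, 375_000, 10_000, 125_000)


def render_training_field(n_cells: int, seed: int, cfg: sc.RenderConfig):
    """One rendered column projection plus its ground-truth mask."""
    spec = sc.ScaffoldSpec(volume_ul=500.0, n_cells=n_cells)
    points = sc.generate_points(spec, seed=seed)
    column = sc.design_columns(spec, seed=seed).columns[0]
    stack = sc.render_stack(points, column, cfg, seed=seed)
    image = sc.max_project(sc.to_8bit(stack))
    truth = sc.ground_truth_projection_mask(points, column, cfg)
    return image, truth, points, column


@pytest.fixture(scope="session")
def render_cfg() -> sc.RenderConfig:
    return sc.RenderConfig()


@pytest.fixture(scope="session")
def trained_model(render_cfg, tmp_path_factory):
    """Pixel classifier trained on six images spanning all densities."""
    images, label_masks = [], []
    for i, n in enumerate(TRAIN_DENSITIES):
        image, truth, _, _ = render_training_field(n, seed=100 + i, cfg=render_cfg)
        images.append(image)
        label_masks.append(
            sc.sample_training_labels(truth, n_per_class=4000, seed=400 + i)
        )
    model = sc.train_pixel_classifier(images, label_masks, seed=0)
    path = tmp_path_factory.mktemp("model") / "classifier.joblib"
    model.save(path)
    return model, path
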