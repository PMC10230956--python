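"""Shared fixtures: RNGs, tiny scenes, and a desk-scale model."""

import numpy as np
import pytest

from secotr.model import SECOTR, tiny_model_config
from secotr.synthetic import tiny_scene_config, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Eight deterministic 128-px scenes with ground truth."""
    cfg = tiny_scene_config(seed=7)
    return [generate_scene(cfg, i) for i in range(8)]


@pytest.fixture(scope="session")
def tiny_model():
    return SECOTR(tiny_model_config(), seed=0)


def random_blob_mask(rng, h, w, r_range=(4, 14)):
    """Random filled ellipse mask; may touch borders."""
    from skimage.draw import ellipse
    m = np.zeros((h, w), dtype=bool)
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    ra, rb = rng.uniform(*r_range), rng.uniform(*r_range)
    rr, cc = ellipse(cy, cx, ra, rb, shape=(h, w))
    m[rr, cc] = True
    return m
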