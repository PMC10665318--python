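import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from mdrs import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disk_scene():
    """One noise-free 25 um opaque disk on a light background."""
    element = synthetic.make_sphere(synthetic.ShapeSpec("sphere", 25.0))
    return synthetic.compose_scene([element], image_size=(64, 64), seed=1)


@pytest.fixture
def flake_scene():
    """20 translucent flakes, noise-free, with ground truth."""
    elements = synthetic.flake_population(20, median_ecd=30.0, gsd=1.3, seed=3)
    return synthetic.compose_scene(elements, image_size=(800, 800), seed=4)


def random_simple_polygon(rng, n_vertices=12, radius=10.0):
    """Random star-convex polygon (simple by construction)."""
    theta = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_vertices))
    radii = radius * rng.uniform(0.4, 1.0, n_vertices)
    return np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
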