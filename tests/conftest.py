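"""Shared fixtures: synthetic images and session-trained pipeline models.

The trained models are fitted once per session on two sibling synthetic
images (same morphology parameters, different seeds) and reused by the
detector-quality, pipeline and tiling tests.
"""

import numpy as np
import pytest

from myoseg.hierarchy import EnergyModel, Node, RegionTree
from myoseg.pipeline import PipelineConfig, train_models
from myoseg.synthetic import SyntheticSpec, generate_image

EVAL_SEED = 7

# study conditions of the easy end-to-end recovery check: clear boundaries,
# no broken contours
EASY_SPEC = SyntheticSpec(
    height=512,
    width=512,
    n_cells=30,
    boundary_contrast=0.6,
    boundary_break_prob=0.0,
    seed=EVAL_SEED,
)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def eval_image():
    """Held-out easy synthetic image with ground truth."""
    return generate_image(EASY_SPEC)


@pytest.fixture(scope="session")
def train_pairs():
    """Two sibling training images (same spec, different seeds)."""
    import dataclasses

    return [
        generate_image(dataclasses.replace(EASY_SPEC, seed=EVAL_SEED + k))
        for k in (1, 2)
    ]


@pytest.fixture(scope="session")
def trained_models(train_pairs, default_config):
    return train_models(train_pairs, default_config)


@pytest.fixture(scope="session")
def small_image():
    """Smaller/cheaper synthetic fixture for unit-level pipeline tests."""
    spec = SyntheticSpec(
        height=256,
        width=256,
        n_cells=10,
        boundary_contrast=0.6,
        boundary_break_prob=0.0,
        seed=3,
    )
    return generate_image(spec)


def make_random_tree(rng, n_leaves):
    """Random binary merge tree over leaves 1..n plus a random energy model.

    Returns (tree, model) with uniform random node scores and random
    pairwise edges along a random leaf chain.
    """
    nodes = {i: Node(id=i, region_label=i) for i in range(1, n_leaves + 1)}
    roots = list(range(1, n_leaves + 1))
    next_id = n_leaves + 1
    while len(roots) > 1:
        i = rng.integers(0, len(roots))
        a = roots.pop(int(i))
        j = rng.integers(0, len(roots))
        b = roots.pop(int(j))
        nodes[next_id] = Node(id=next_id, left=min(a, b), right=max(a, b))
        roots.append(next_id)
        next_id += 1
    tree = RegionTree(nodes=nodes, root=roots[0])
    scores = {nid: float(rng.uniform(0.02, 0.98)) for nid in nodes}
    leaves = list(range(1, n_leaves + 1))
    rng.shuffle(leaves)
    pairwise = [
        (min(a, b), max(a, b), float(rng.uniform(0, 1)), int(rng.integers(1, 30)))
        for a, b in zip(leaves, leaves[1:])
    ]
    return tree, scores, pairwise


@pytest.fixture
def random_tree_factory():
    return make_random_tree
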