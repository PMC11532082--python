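"""Shared fixtures: small hand-built trees and random synthetic neurons."""

from __future__ import annotations

import io

import numpy as np
import pytest

from neurofuse.swc import NeuronNode, NeuronTree, read_swc
from neurofuse.synthetic import MorphoClassParams, generate_neuron


def make_tree(rows, name="fixture"):
    """Build a NeuronTree from (id, type, x, y, z, r, parent) tuples."""
    return NeuronTree(
        [NeuronNode(i, t, (x, y, z), r, p) for i, t, x, y, z, r, p in rows],
        name=name,
    )


@pytest.fixture
def chain_tree():
    # soma -> a -> b straight chain along z
    return make_tree(
        [
            (1, 1, 0.0, 0.0, 0.0, 1.0, -1),
            (2, 3, 0.0, 0.0, 1.0, 0.5, 1),
            (3, 3, 0.0, 0.0, 3.0, 0.5, 2),
        ]
    )


@pytest.fixture
def y_tree():
    # one bifurcation with orthogonal daughters in the x-y plane
    return make_tree(
        [
            (1, 1, 0.0, 0.0, 0.0, 2.0, -1),
            (2, 3, 0.0, 0.0, 2.0, 1.0, 1),
            (3, 3, 1.0, 0.0, 2.0, 0.5, 2),
            (4, 3, 0.0, 1.0, 2.0, 0.5, 2),
        ]
    )


@pytest.fixture
def swc_text():
    return (
        "# comment line one\n"
        "# comment line two\n"
        "1 1 0 0 0 1 -1\n"
        "2 3 0 0 1 0.5 1\n"
        "3 3 0 0 2 0.5 2\n"
    )


@pytest.fixture
def random_trees():
    """20 random synthetic neurons spanning the parameter space."""
    trees = []
    base = MorphoClassParams(label="mix")
    variants = [
        base,
        MorphoClassParams(label="mix", bifurcation_prob=0.25, tortuosity=0.5,
                          n_stems=2, max_nodes=150),
        MorphoClassParams(label="mix", segment_length_mean=20.0, taper_rate=0.7,
                          n_stems=4, max_nodes=120),
        MorphoClassParams(label="mix", bifurcation_prob=0.05, tortuosity=0.15,
                          max_nodes=200),
        MorphoClassParams(label="mix", n_stems=1, bifurcation_prob=0.2,
                          max_nodes=100),
    ]
    for i in range(20):
        trees.append(generate_neuron(variants[i % len(variants)], seed=100 + i))
    return trees


def rigid_motion(rng: np.random.Generator):
    """A random proper rotation matrix and translation vector."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=50.0, size=3)
    return q, t


def transform_tree(tree, q, t, scale: float = 1.0):
    xyz = tree.coordinates() * scale @ q.T + t
    nodes = [
        NeuronNode(n.id, n.type_code, tuple(map(float, p)), n.radius * scale, n.parent_id)
        for n, p in zip(tree.nodes, xyz)
    ]
    return NeuronTree(nodes, name=tree.name, class_label=tree.class_label)


def parse(text: str):
    return read_swc(io.StringIO(text))
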