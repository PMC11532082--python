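"""Synthetic neuron morphology generator.

Grows labeled SWC-style trees with controllable class statistics so the full
pipeline (morphometrics, projection, training) can be exercised end to end.
The growth model is a stochastic recursive elongation: segments extend with
per-step angular jitter (cone sampling around the current direction),
bifurcate as a Bernoulli event per step with daughter directions separated
by a sampled bifurcation angle, and taper their diameter at each
bifurcation.  This is deliberately simple — rich enough to make every
registry morphometric non-degenerate, not a biophysical growth simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .swc import NeuronNode, NeuronTree

__all__ = ["MorphoClassParams", "generate_neuron", "generate_dataset", "default_class_params"]


@dataclass(frozen=True)
class MorphoClassParams:
    """Growth parameters defining one synthetic neuron class."""

    label: str
    n_stems: int = 3
    bifurcation_prob: float = 0.12
    segment_length_mean: float = 12.0  # micrometers per step
    segment_length_sd: float = 3.0
    tortuosity: float = 0.35  # per-step angular jitter, radians
    bifurcation_angle_mean: float = math.radians(60.0)
    taper_rate: float = 0.85  # diameter multiplier per bifurcation, in (0, 1]
    initial_radius: float = 1.5
    soma_radius: float = 6.0
    max_depth: int = 6
    max_nodes: int = 400

    def __post_init__(self) -> None:
        if not 0.0 <= self.bifurcation_prob <= 1.0:
            raise ValueError("bifurcation_prob must lie in [0, 1]")
        if self.segment_length_mean <= 0 or self.segment_length_sd < 0:
            raise ValueError("segment lengths must be positive")
        if not 0.0 < self.taper_rate <= 1.0:
            raise ValueError("taper_rate must lie in (0, 1]")
        if self.n_stems < 1 or self.max_nodes < 2 or self.max_depth < 1:
            raise ValueError("n_stems >= 1, max_depth >= 1, max_nodes >= 2 required")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _jitter(direction: np.ndarray, angle_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``direction`` by a random angle ~ |N(0, angle_sd)| about a random
    perpendicular axis (cone sampling)."""
    if angle_sd == 0:
        return direction
    theta = abs(rng.normal(0.0, angle_sd))
    return _rotate_from(direction, theta, rng)


def _rotate_from(direction: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    d = _unit(direction)
    # random axis perpendicular to d
    r = rng.normal(size=3)
    axis = r - np.dot(r, d) * d
    n = np.linalg.norm(axis)
    if n < 1e-12:
        axis = np.array([d[1], -d[0], 0.0])
        if np.linalg.norm(axis) < 1e-12:
            axis = np.array([1.0, 0.0, 0.0])
        n = np.linalg.norm(axis)
    axis = axis / n
    return d * math.cos(theta) + np.cross(axis, d) * math.sin(theta)


def generate_neuron(params: MorphoClassParams, seed: int) -> NeuronTree:
    """Grow one synthetic neuron; identical ``(params, seed)`` give identical trees."""
    rng = np.random.default_rng(seed)
    nodes: list[NeuronNode] = [
        NeuronNode(1, 1, (0.0, 0.0, 0.0), params.soma_radius, -1)
    ]
    next_id = 2

    # stems leave the soma in well-spread directions (jittered sphere points)
    base_dirs = _spread_directions(params.n_stems, rng)

    # grow stems breadth-first; each entry: (parent_id, position, direction, radius, depth)
    frontier = [
        (1, np.zeros(3), d, params.initial_radius, 1) for d in base_dirs
    ]
    while frontier and next_id <= params.max_nodes:
        parent_id, pos, direction, radius, depth = frontier.pop(0)
        steplen = max(
            0.1 * params.segment_length_mean,
            rng.normal(params.segment_length_mean, params.segment_length_sd),
        )
        direction = _jitter(direction, params.tortuosity, rng)
        new_pos = pos + direction * steplen
        node = NeuronNode(
            next_id, 3, tuple(float(v) for v in new_pos), radius, parent_id
        )
        nodes.append(node)
        nid = next_id
        next_id += 1
        if next_id > params.max_nodes:
            break
        bifurcate = (
            depth < params.max_depth
            and rng.random() < params.bifurcation_prob
        )
        if bifurcate:
            half = 0.5 * abs(rng.normal(params.bifurcation_angle_mean, 0.2))
            d1 = _rotate_from(direction, half, rng)
            # second daughter on the roughly opposite side of the cone
            d2 = _unit(2.0 * np.dot(direction, d1) * direction - d1)
            d2 = _jitter(d2, 0.05, rng)
            r_child = radius * params.taper_rate
            frontier.append((nid, new_pos, d1, r_child, depth + 1))
            frontier.append((nid, new_pos, d2, r_child, depth + 1))
        else:
            frontier.append((nid, new_pos, direction, radius, depth))

    if len(nodes) < 2:
        raise ValueError("parameters cannot produce a tree with >= 2 nodes")
    tree = NeuronTree(nodes, name=f"{params.label}-{seed}", class_label=params.label)
    return tree


def _spread_directions(k: int, rng: np.random.Generator) -> list[np.ndarray]:
    dirs = []
    for i in range(k):
        # latitude band + random azimuth keeps stems apart but randomized
        phi = rng.uniform(0, 2 * math.pi)
        cos_t = -1.0 + 2.0 * (i + rng.uniform(0.2, 0.8)) / k
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t**2))
        dirs.append(np.array([sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t]))
    return dirs


def generate_dataset(
    class_params: list[MorphoClassParams],
    n_per_class: int,
    seed: int,
) -> tuple[list[NeuronTree], list[str]]:
    """Balanced labeled dataset: ``n_per_class`` trees per class.

    Each neuron draws its randomness from a stream derived from
    ``(seed, class index, neuron index)``, so generation is reproducible and
    order-independent.
    """
    trees: list[NeuronTree] = []
    labels: list[str] = []
    for ci, params in enumerate(class_params):
        for j in range(n_per_class):
            sub = np.random.SeedSequence([seed, ci, j]).generate_state(1)[0]
            trees.append(generate_neuron(params, int(sub) % (2**31)))
            labels.append(params.label)
    return trees, labels


def default_class_params(n_classes: int = 3) -> list[MorphoClassParams]:
    """Well-separated default classes for desk-scale experiments.

    Classes differ in total arbor length and branching density (roughly 2x
    steps between classes), the axes on which real neuron types separate
    most strongly.
    """
    base = MorphoClassParams(label="type_a")
    variants = [
        base,
        replace(base, label="type_b", segment_length_mean=24.0,
                bifurcation_prob=0.06, tortuosity=0.2, n_stems=2),
        replace(base, label="type_c", bifurcation_prob=0.3,
                tortuosity=0.55, n_stems=5, taper_rate=0.7),
        replace(base, label="type_d", segment_length_mean=6.0,
                bifurcation_prob=0.2, n_stems=4, max_depth=8),
        replace(base, label="type_e", segment_length_mean=18.0,
                bifurcation_prob=0.02, tortuosity=0.1, n_stems=1),
    ]
    if not 1 <= n_classes <= len(variants):
        raise ValueError(f"n_classes must lie in [1, {len(variants)}]")
    return variants[:n_classes]
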