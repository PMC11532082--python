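"""Morphometric registry: closed forms, oracle agreement, invariances."""

import math

import numpy as np
import pytest

from neurofuse.morphometrics import (
    EXTENT_METRICS,
    METRIC_NAMES,
    METRIC_SCALE_POWERS,
    compute_feature_vector,
    decompose_branches,
    metric_bifurcation_angle,
    metric_contraction,
    metric_diameter_ratios,
    metric_partition_asymmetry,
    metric_total_length,
)

from conftest import make_tree, rigid_motion, transform_tree
from oracles import oracle_metrics, branches_of, from_tree


class TestBranchDecomposition:
    def test_single_chain_is_one_stem_branch(self, chain_tree):
        branches = decompose_branches(chain_tree)
        assert len(branches) == 1
        assert branches[0].order == 1
        assert [n.id for n in branches[0].nodes] == [1, 2, 3]

    def test_bifurcation_gives_three_branches(self, y_tree):
        branches = decompose_branches(y_tree)
        orders = sorted(b.order for b in branches)
        assert len(branches) == 3
        assert orders == [1, 2, 2]

    def test_branch_count_matches_recursive_oracle(self, random_trees):
        for tree in random_trees:
            got = decompose_branches(tree)
            expected = branches_of(from_tree(tree))
            assert len(got) == len(expected)
            # stems + 2 * bifurcations for binary trees
            assert len(got) == len(tree.stems()) + 2 * len(tree.bifurcations())

    def test_branches_partition_edges(self, random_trees):
        for tree in random_trees[:8]:
            branches = decompose_branches(tree)
            total = sum(b.path_length for b in branches)
            assert total == pytest.approx(metric_total_length(tree), rel=1e-9)


class TestClosedForms:
    def test_total_length_chain(self, chain_tree):
        assert metric_total_length(chain_tree) == pytest.approx(3.0)

    def test_total_length_single_node(self):
        tree = make_tree([(1, 1, 0, 0, 0, 1.0, -1)])
        assert metric_total_length(tree) == 0.0

    def test_straight_branch_contraction_is_one(self, chain_tree):
        (branch,) = decompose_branches(chain_tree)
        assert metric_contraction(branch) == pytest.approx(1.0)

    def test_right_angle_contraction(self):
        tree = make_tree(
            [
                (1, 1, 0, 0, 0, 1, -1),
                (2, 3, 1, 0, 0, 0.5, 1),
                (3, 3, 1, 1, 0, 0.5, 2),
            ]
        )
        (branch,) = decompose_branches(tree)
        assert metric_contraction(branch) == pytest.approx(math.sqrt(2) / 2)

    def test_zero_length_branch_contraction_raises(self):
        tree = make_tree(
            [(1, 1, 0, 0, 0, 1, -1), (2, 3, 0, 0, 0, 0.5, 1)]
        )
        (branch,) = decompose_branches(tree)
        with pytest.raises(ValueError):
            metric_contraction(branch)

    def test_partition_asymmetry_balanced_and_lopsided(self):
        # balanced: 2 tips vs 2 tips -> 0 ; lopsided (3, 1) -> 1
        balanced = make_tree(
            [
                (1, 1, 0, 0, 0, 1, -1), (2, 3, 0, 0, 1, 1, 1),
                (3, 3, -1, 0, 2, 1, 2), (4, 3, 1, 0, 2, 1, 2),
                (5, 3, -2, 0, 3, 1, 3), (6, 3, -1, 1, 3, 1, 3),
                (7, 3, 2, 0, 3, 1, 4), (8, 3, 1, 1, 3, 1, 4),
            ]
        )
        assert metric_partition_asymmetry(balanced, 2) == 0.0
        lopsided = make_tree(
            [
                (1, 1, 0, 0, 0, 1, -1), (2, 3, 0, 0, 1, 1, 1),
                (3, 3, -1, 0, 2, 1, 2),  # subtree with 3 tips
                (4, 3, 1, 0, 2, 1, 2),   # single tip
                (5, 3, -2, 0, 3, 1, 3), (6, 3, -1, 1, 3, 1, 3),
                (7, 3, -3, 0, 4, 1, 5), (8, 3, -2, 1, 4, 1, 5),
            ]
        )
        assert metric_partition_asymmetry(lopsided, 2) == pytest.approx(1.0)

    def test_orthogonal_bifurcation_angle(self, y_tree):
        assert metric_bifurcation_angle(y_tree, 2, "local") == pytest.approx(90.0)

    def test_opposite_daughters_angle_is_180(self):
        tree = make_tree(
            [
                (1, 1, 0, 0, 0, 1, -1), (2, 3, 0, 0, 1, 1, 1),
                (3, 3, 1, 0, 1, 1, 2), (4, 3, -1, 0, 1, 1, 2),
            ]
        )
        assert metric_bifurcation_angle(tree, 2, "local") == pytest.approx(180.0)

    def test_diameter_ratios(self, y_tree):
        # daughters d=1, 1; parent d=2
        ratio, pd = metric_diameter_ratios(y_tree, 2)
        assert ratio == pytest.approx(1.0)
        assert pd == pytest.approx(0.5)

    def test_unequal_daughter_ratio(self):
        tree = make_tree(
            [
                (1, 1, 0, 0, 0, 2, -1), (2, 3, 0, 0, 1, 1.5, 1),
                (3, 3, 1, 0, 1, 1.0, 2), (4, 3, -1, 0, 1, 0.5, 2),
            ]
        )
        ratio, _ = metric_diameter_ratios(tree, 2)
        assert ratio == pytest.approx(2.0)


class TestFeatureVector:
    def test_vector_has_43_named_finite_entries(self, random_trees):
        vec = compute_feature_vector(random_trees[0])
        assert len(vec) == 43
        assert vec.names == METRIC_NAMES
        assert np.all(np.isfinite(vec.values))

    def test_degenerate_chain_counts_and_mask(self, chain_tree):
        vec = compute_feature_vector(chain_tree)
        d = vec.as_dict()
        assert d["N_bifs"] == 0 and d["N_tips"] == 1 and d["N_stems"] == 1
        # angle metrics undefined without a bifurcation: zero + masked out
        masked = {n for n, m in zip(vec.names, vec.mask) if not m}
        assert "Bif_ampl_local" in masked
        assert d["Bif_ampl_local"] == 0.0

    def test_every_metric_matches_oracle_on_random_trees(self, random_trees):
        """All 43 registry metrics vs the independent brute-force oracle."""
        for tree in random_trees:
            expected = oracle_metrics(tree)
            vec = compute_feature_vector(tree)
            for name, value, defined in zip(vec.names, vec.values, vec.mask):
                exp = expected[name]
                if exp is None:
                    assert not defined, f"{name} should be undefined on {tree.name}"
                else:
                    assert defined, f"{name} should be defined on {tree.name}"
                    assert value == pytest.approx(exp, rel=1e-6, abs=1e-9), (
                        f"{name} mismatch on {tree.name}"
                    )


class TestInvariances:
    def test_rigid_motion_leaves_non_extent_metrics_unchanged(self, random_trees):
        rng = np.random.default_rng(42)
        for tree in random_trees[:6]:
            q, t = rigid_motion(rng)
            moved = transform_tree(tree, q, t)
            v0 = compute_feature_vector(tree)
            v1 = compute_feature_vector(moved)
            for name, a, b in zip(v0.names, v0.values, v1.values):
                if name in EXTENT_METRICS:
                    continue
                assert a == pytest.approx(b, rel=1e-5, abs=1e-6), name

    def test_extent_metrics_translation_invariant_not_rotation(self, random_trees):
        tree = random_trees[0]
        shifted = transform_tree(tree, np.eye(3), np.array([10.0, -5.0, 3.0]))
        v0, v1 = compute_feature_vector(tree), compute_feature_vector(shifted)
        for name in EXTENT_METRICS:
            i = METRIC_NAMES.index(name)
            assert v0.values[i] == pytest.approx(v1.values[i], rel=1e-9)
        # a generic rotation changes at least one bounding-box extent
        rng = np.random.default_rng(7)
        q, _ = rigid_motion(rng)
        rotated = transform_tree(tree, q, np.zeros(3))
        v2 = compute_feature_vector(rotated)
        diffs = [
            abs(v0.values[METRIC_NAMES.index(n)] - v2.values[METRIC_NAMES.index(n)])
            for n in EXTENT_METRICS
        ]
        assert max(diffs) > 1e-3

    def test_uniform_scaling_follows_dimension(self, random_trees):
        s = 2.5
        for tree in random_trees[:4]:
            scaled = transform_tree(tree, np.eye(3), np.zeros(3), scale=s)
            v0, v1 = compute_feature_vector(tree), compute_feature_vector(scaled)
            for name, a, b, defined in zip(v0.names, v0.values, v1.values, v0.mask):
                if not defined:
                    continue
                power = METRIC_SCALE_POWERS[name]
                assert b == pytest.approx(a * s**power, rel=1e-5, abs=1e-6), name
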