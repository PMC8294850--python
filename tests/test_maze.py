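"""Labyrinth structure, symmetry maps, and geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from treemaze.maze import (MazeConfig, MazeError, build_maze, classify_rings,
                           control_nodes, decision_complexity_bits, image_node,
                           leaf_to_turns, mirror_node, shortest_path,
                           tree_distance, turns_to_leaf)


def test_structure_counts(maze):
    assert maze.n_nodes == 127
    assert len(maze.junctions) == 63
    assert len(maze.leaves) == 64
    assert all(len(maze.adjacency[j]) == 3 for j in maze.junctions if j != 0)
    assert len(maze.adjacency[0]) == 2          # entrance corridor is no node
    assert all(len(maze.adjacency[l]) == 1 for l in maze.leaves)
    assert all(maze.level[l] == 6 for l in maze.leaves)


def test_smallest_tree():
    m = build_maze(MazeConfig(n_junction_levels=1))
    assert m.n_nodes == 3
    assert m.junctions == [0] and m.leaves == [1, 2]


def test_invalid_config_rejected():
    with pytest.raises(MazeError):
        build_maze(MazeConfig(n_junction_levels=0))


def test_heap_parent_consistency(maze):
    for i in range(1, maze.n_nodes):
        assert maze.parent(i) == (i - 1) // 2
        assert i in maze.adjacency[(i - 1) // 2]


def test_turn_sequences_bijective(maze):
    seqs = {leaf_to_turns(maze, leaf) for leaf in maze.leaves}
    assert len(seqs) == 64
    for leaf in maze.leaves:
        assert turns_to_leaf(maze, leaf_to_turns(maze, leaf)) == leaf
    assert leaf_to_turns(maze, 0) == ()


@settings(max_examples=60, deadline=None)
@given(a=st.integers(0, 126), b=st.integers(0, 126), c=st.integers(0, 126))
def test_tree_distance_is_metric(a, b, c):
    maze = build_maze(MazeConfig())
    dab = tree_distance(maze, a, b)
    assert dab == tree_distance(maze, b, a)
    assert (dab == 0) == (a == b)
    assert dab <= tree_distance(maze, a, c) + tree_distance(maze, c, b)
    # distance equals the level formula through the common ancestor
    path = shortest_path(maze, a, b)
    assert len(path) - 1 == dab
    lca_level = min(maze.level[n] for n in path)
    assert dab == maze.level[a] + maze.level[b] - 2 * lca_level


def test_key_distances(maze):
    w = maze.water_port_leaf
    assert tree_distance(maze, 0, w) == 6
    assert tree_distance(maze, w, w) == 0
    assert tree_distance(maze, w, image_node(maze, w)) == 12
    assert max(tree_distance(maze, w, l) for l in maze.leaves) == 12


def test_image_node_properties(maze):
    for leaf in maze.leaves:
        img = image_node(maze, leaf)
        assert img != leaf
        assert image_node(maze, img) == leaf              # involution
        assert tree_distance(maze, leaf, img) == 12
        # image is the 180-degree rotation in the embedding
        x, y = maze.cell_coords[leaf]
        assert maze.cell_coords[img] == (-x, -y)
    # first turn flipped, rest unchanged
    leaf = maze.leaves[5]
    t = leaf_to_turns(maze, leaf)
    ti = leaf_to_turns(maze, image_node(maze, leaf))
    assert ti[0] != t[0] and ti[1:] == t[1:]
    with pytest.raises(MazeError):
        image_node(maze, 0)


def test_control_nodes_group_action(maze):
    for leaf in maze.leaves:
        controls = control_nodes(maze, leaf)
        assert len(controls) == 3 and leaf not in controls
        assert image_node(maze, leaf) in controls
        assert mirror_node(maze, leaf) in controls
        for c in controls:
            assert leaf in control_nodes(maze, c)         # closure


def test_ring_classification(maze):
    rings = classify_rings(maze)
    counts = {k: sum(1 for v in rings.values() if v == k)
              for k in ("outer", "inner", "middle")}
    assert counts == {"outer": 28, "inner": 16, "middle": 20}
    # water port and its sibling both sit in the outer ring
    w = maze.water_port_leaf
    sibling = w + 1 if w % 2 == 1 else w - 1
    assert rings[w] == "outer" and rings[sibling] == "outer"
    # rings invariant under the 180-degree rotation
    for leaf in maze.leaves:
        assert rings[leaf] == rings[image_node(maze, leaf)]


def test_decision_complexity_bits():
    assert math.isclose(decision_complexity_bits(1), math.log2(3))
    assert round(decision_complexity_bits(6), 1) == 9.5
    assert round(decision_complexity_bits(63)) == 100


def test_serialization_stable(maze):
    js = maze.to_json()
    assert js == maze.to_json()
    assert '"n_junction_levels": 6' in js
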