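"""Track reduction, bouts, direct paths, and error counting."""

import numpy as np
import pytest

from treemaze.biases import BiasSet
from treemaze.maze import shortest_path
from treemaze.reduction import (CAGE, KeypointTrack, NodeSequence,
                                count_errors, count_visits, find_direct_paths,
                                home_run, maze_time, path_overlap,
                                segment_bouts, to_node_sequence)
from treemaze.synth import PolicyProfile, SessionRecipe, generate_session, \
    render_track


def seq_of(nodes, dt=1.0):
    return NodeSequence(np.array(nodes), dt * np.arange(len(nodes)))


# ---------------------------------------------------------------------
# track -> node sequence
# ---------------------------------------------------------------------

def test_empty_track_empty_sequence(maze):
    track = KeypointTrack(np.empty(0), np.empty(0), np.empty(0))
    assert len(to_node_sequence(track, maze)) == 0


def test_dwell_and_jitter_single_event(maze):
    # nose sits in the root cell, pokes into the corridor, and returns:
    # a single node event
    t = np.arange(10) * 0.1
    x = np.array([0, 0.1, 0.3, 0.6, 0.8, 0.9, 0.6, 0.2, 0.0, 0.1])
    y = np.zeros(10)
    seq = to_node_sequence(KeypointTrack(t, x, y), maze)
    assert list(seq.nodes) == [0]


def test_track_along_corridor_yields_path(maze):
    # straight glide from the root to a level-6 leaf passes 7 nodes
    leaf = maze.leaves[0]
    path = shortest_path(maze, 0, leaf)
    pts = []
    for a, b in zip(path[:-1], path[1:]):
        xa, ya = maze.cell_coords[a]
        xb, yb = maze.cell_coords[b]
        for f in np.linspace(0, 1, 20, endpoint=False):
            pts.append((xa + f * (xb - xa), ya + f * (yb - ya)))
    pts.append(maze.cell_coords[leaf])
    xs, ys = np.array(pts).T
    seq = to_node_sequence(KeypointTrack(np.arange(len(xs)) * 0.02, xs, ys),
                           maze)
    assert list(seq.nodes) == path
    assert len(seq) == 7


def test_teleport_policies(maze):
    x3, y3 = (float(c) for c in maze.cell_coords[3])
    track = KeypointTrack(np.array([0.0, 0.03, 1.0, 1.03]),
                          np.array([0.0, 0.0, x3, x3]),
                          np.array([0.0, 0.0, y3, y3]), frame_rate=30.0)
    with pytest.warns(UserWarning, match="teleport"):
        seq = to_node_sequence(track, maze, repair="split")
    assert list(seq.nodes) == [0, 3]
    with pytest.warns(UserWarning, match="teleport"):
        seq = to_node_sequence(track, maze, repair="interpolate")
    assert list(seq.nodes) == shortest_path(maze, 0, 3)
    seq.validate(maze)


def test_simulated_session_round_trip(maze):
    """Agent walk -> synthetic track -> reduction reproduces the walk."""
    prof = PolicyProfile(explore_biases=BiasSet(0.85, 0.55, 0.90, 0.60))
    rec = SessionRecipe(duration=1200.0, schedule=((0.0, prof),), seed=3)
    sess = generate_session(maze, rec)
    track = render_track(sess, maze, frame_rate=30.0, jitter=0.0)
    red = to_node_sequence(track, maze)
    truth = sess.seq.nodes[sess.seq.nodes != CAGE]
    assert list(red.nodes) == list(truth)


# ---------------------------------------------------------------------
# bouts and direct paths
# ---------------------------------------------------------------------

def test_segment_bouts_basic(maze):
    seq = seq_of([CAGE, 0, 1, 0, CAGE, 0, 2, 0, CAGE, 0, 1, 0])
    bouts = segment_bouts(seq)
    assert len(bouts) == 3
    for b in bouts:
        assert b.nodes[0] == 0 and b.nodes[-1] == 0
        assert b.entry_time < b.exit_time
    assert segment_bouts(seq_of([])) == []


def test_maze_time_excises_cage(maze):
    seq = seq_of([CAGE, 0, 1, 0, CAGE, CAGE, 0, 1])
    mt = maze_time(seq)
    assert mt[0] == 0
    assert mt[-1] == 3 + 1  # 3 s of first bout (0->..->cage) + 1 s of second


def test_direct_path_junction_threshold(maze):
    w = maze.water_port_leaf
    perfect = shortest_path(maze, 0, w)           # 7 nodes, 6 junctions
    seq = seq_of([CAGE] + perfect + [CAGE])
    assert find_direct_paths(seq, w, 6, maze) == []     # ">6" excludes it
    assert len(find_direct_paths(seq, w, 5, maze)) == 1

    far = [l for l in maze.leaves
           if len(shortest_path(maze, l, w)) == 13][0]
    long_run = shortest_path(maze, far, w)        # 13 nodes, 11 junctions
    seq = seq_of([CAGE, 0] + shortest_path(maze, 0, far)[1:] + long_run[1:]
                 + [CAGE])
    paths = find_direct_paths(seq, w, 6, maze)
    assert len(paths) == 1
    assert paths[0].junction_count(maze) == 11


def test_direct_path_truncated_at_reversal(maze):
    w = maze.water_port_leaf
    p = shortest_path(maze, 0, w)
    # insert a reversal two steps before the target
    nodes = p[:-1] + p[-3:]
    seq = seq_of([CAGE] + nodes + [CAGE])
    paths = find_direct_paths(seq, w, 0, maze)
    assert len(paths) == 1
    assert paths[0].nodes == p[-3:]


def test_count_errors():
    assert count_errors(6, 6) == 0
    assert count_errors(8, 6) == 1
    assert count_errors(20, 6) == 7
    with pytest.raises(ValueError):
        count_errors(7, 6)
    with pytest.raises(ValueError):
        count_errors(5, 6)


def test_home_run_levels(maze):
    leaf = maze.leaves[10]
    out = shortest_path(maze, 0, leaf)
    bout = segment_bouts(seq_of([CAGE] + out + out[-2::-1] + [CAGE]))[0]
    hr, level = home_run(bout, maze)
    assert level == 6 and hr.nodes[0] == leaf and hr.nodes[-1] == 0
    # last step reverses at level 1 -> home run of one step
    bout = segment_bouts(seq_of([CAGE, 0, 1, 0, CAGE]))[0]
    hr, level = home_run(bout, maze)
    assert level == 1 and hr.nodes == [1, 0]


def test_path_overlap(maze):
    p = shortest_path(maze, 0, maze.water_port_leaf)
    assert path_overlap(p, p[::-1]) == 7
    left = shortest_path(maze, 0, maze.leaves[0])      # left subtree
    right = shortest_path(maze, 0, maze.leaves[-1])    # right subtree
    assert path_overlap(left, right) == 1              # only the root


def test_two_step_visit_rule(maze):
    leaf = maze.leaves[0]
    parent = (leaf - 1) // 2
    grand = (parent - 1) // 2
    flicker = seq_of([CAGE, leaf, parent, leaf, parent, leaf, CAGE])
    assert count_visits(flicker, leaf, maze, two_step=True) == 1
    away = seq_of([CAGE, leaf, parent, grand, parent, leaf, CAGE])
    assert count_visits(away, leaf, maze, two_step=True) == 2
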