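"""Binary-tree labyrinth model.

The maze is a full binary tree of T-junctions: ``L`` junction levels
(default 6) give ``2**L - 1`` junctions and ``2**L`` end nodes, 127 nodes
in all for the default depth.  Nodes are heap-indexed: the central
junction (maze entrance) is node 0 and the children of junction ``i`` are
``2*i + 1`` (left branch) and ``2*i + 2`` (right branch).  End nodes are
the ids ``2**L - 1 .. 2**(L+1) - 2``.

A deterministic H-tree embedding places every node on a square grid
(units of one corridor width, physically 1.5 inch).  Corridor lengths
halve every two levels so the 64 end nodes of the default maze land on a
regular 8x8 lattice.  The embedding is used only for ring classification
and for synthesizing continuous tracks; all graph logic is arithmetic on
heap indices.

Junction levels are numbered 0..L-1 from the central junction, end nodes
sit at level L.  (Figures elsewhere sometimes use a 1-based convention
with end nodes at level 7; use :func:`level_to_reporting` to relabel.)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx

__all__ = [
    "MazeConfig",
    "MazeGraph",
    "build_maze",
    "tree_distance",
    "image_node",
    "mirror_node",
    "control_nodes",
    "classify_rings",
    "turns_to_leaf",
    "leaf_to_turns",
    "decision_complexity_bits",
    "level_to_reporting",
]

LEFT = "L"
RIGHT = "R"

#: Corridor length (grid cells) from a junction at depth d to its children.
#: Lengths halve every two levels so leaves tile a regular lattice.
_SEGMENT_LENGTHS = {0: 4, 1: 4, 2: 2, 3: 2, 4: 1, 5: 1}


class MazeError(ValueError):
    """Invalid maze configuration or node lookup."""


@dataclass(frozen=True)
class MazeConfig:
    """Parameters of the labyrinth.

    Parameters
    ----------
    n_junction_levels:
        Number of T-junction levels (6 in the study maze).
    water_port_leaf:
        Node id of the rewarded end node, or None to use the default
        (an outer-ring leaf adjacent to a corner; the physical maze's
        port location is an arbitrary documented choice here).
    cell_pitch:
        Physical grid spacing in inches (1.5 in the study maze).
    embedding:
        Geometric layout scheme; only "h-tree" is implemented.
    """

    n_junction_levels: int = 6
    water_port_leaf: int | None = None
    cell_pitch: float = 1.5
    embedding: str = "h-tree"

    def __post_init__(self) -> None:
        if self.n_junction_levels < 1:
            raise MazeError(
                f"n_junction_levels must be >= 1, got {self.n_junction_levels}"
            )
        if self.embedding != "h-tree":
            raise MazeError(f"unknown embedding {self.embedding!r}")


@dataclass
class MazeGraph:
    """The labyrinth as a tree with geometry and symmetry structure."""

    config: MazeConfig
    n_levels: int
    adjacency: Dict[int, Tuple[int, ...]]
    node_kind: Dict[int, str]          # "junction" | "end_node"
    level: Dict[int, int]
    lr_type: Dict[int, str]            # junction id -> "L" | "R" | "root"
    cell_coords: Dict[int, Tuple[int, int]]
    entry_node: int = 0
    water_port_leaf: int = field(default=-1)
    graph: nx.Graph = field(default_factory=nx.Graph, repr=False)

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return 2 ** (self.n_levels + 1) - 1

    @property
    def junctions(self) -> List[int]:
        return list(range(2 ** self.n_levels - 1))

    @property
    def leaves(self) -> List[int]:
        return list(range(2 ** self.n_levels - 1, 2 ** (self.n_levels + 1) - 1))

    def is_leaf(self, node: int) -> bool:
        self._check(node)
        return node >= 2 ** self.n_levels - 1

    def is_junction(self, node: int) -> bool:
        return not self.is_leaf(node)

    def parent(self, node: int) -> int | None:
        self._check(node)
        return None if node == 0 else (node - 1) // 2

    def children(self, node: int) -> Tuple[int, int] | Tuple[()]:
        self._check(node)
        if self.is_leaf(node):
            return ()
        return (2 * node + 1, 2 * node + 2)

    def branch_type(self, node: int) -> str:
        """Whether *node* hangs off a left or a right branch of its parent."""
        self._check(node)
        if node == 0:
            return "root"
        return LEFT if node % 2 == 1 else RIGHT

    def neighbors(self, node: int) -> Tuple[int, ...]:
        return self.adjacency[node]

    def _check(self, node: int) -> None:
        if not (0 <= node < self.n_nodes):
            raise MazeError(f"unknown node id {node}")

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "config": {
                "n_junction_levels": self.config.n_junction_levels,
                "water_port_leaf": self.water_port_leaf,
                "cell_pitch": self.config.cell_pitch,
                "embedding": self.config.embedding,
            },
            "adjacency": {str(k): list(v) for k, v in sorted(self.adjacency.items())},
            "level": {str(k): v for k, v in sorted(self.level.items())},
            "cell_coords": {str(k): list(v) for k, v in sorted(self.cell_coords.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def build_maze(config: MazeConfig | None = None) -> MazeGraph:
    """Construct the labyrinth graph from its configuration."""
    config = config or MazeConfig()
    L = config.n_junction_levels
    n_nodes = 2 ** (L + 1) - 1
    n_junctions = 2 ** L - 1

    adjacency: Dict[int, Tuple[int, ...]] = {}
    node_kind: Dict[int, str] = {}
    level: Dict[int, int] = {}
    lr_type: Dict[int, str] = {}
    for i in range(n_nodes):
        lvl = int(math.floor(math.log2(i + 1)))
        level[i] = lvl
        neigh: List[int] = []
        if i > 0:
            neigh.append((i - 1) // 2)
        if i < n_junctions:
            node_kind[i] = "junction"
            neigh.extend([2 * i + 1, 2 * i + 2])
            lr_type[i] = "root" if i == 0 else (LEFT if i % 2 == 1 else RIGHT)
        else:
            node_kind[i] = "end_node"
        adjacency[i] = tuple(neigh)

    cell_coords = _h_tree_coordinates(L)

    graph = nx.Graph()
    graph.add_nodes_from(range(n_nodes))
    for i, neigh in adjacency.items():
        for j in neigh:
            graph.add_edge(i, j)

    maze = MazeGraph(
        config=config,
        n_levels=L,
        adjacency=adjacency,
        node_kind=node_kind,
        level=level,
        lr_type=lr_type,
        cell_coords=cell_coords,
        graph=graph,
    )
    if config.water_port_leaf is not None:
        if not maze.is_leaf(config.water_port_leaf):
            raise MazeError(
                f"water_port_leaf {config.water_port_leaf} is not an end node"
            )
        maze.water_port_leaf = config.water_port_leaf
    else:
        maze.water_port_leaf = _default_water_leaf(maze)
    return maze


def _h_tree_coordinates(L: int) -> Dict[int, Tuple[int, int]]:
    """H-tree layout by egocentric left/right turns.

    Each child sits at the parent's position plus the level's corridor
    length along the direction obtained by turning left or right from the
    heading of travel into the parent.  Flipping the first turn while
    keeping the rest therefore maps the layout onto its 180-degree
    rotation, matching the physical maze's symmetry.
    """
    # Corridor lengths: reuse the 6-level table, extending by halving
    # pattern for other depths (lengths scaled so leaves stay distinct).
    if L == 6:
        seg = _SEGMENT_LENGTHS
    else:
        seg = {d: 2 ** ((L - 1 - d) // 2) for d in range(L)}
    coords: Dict[int, Tuple[int, int]] = {0: (0, 0)}
    headings: Dict[int, Tuple[int, int]] = {0: (0, 1)}  # entered heading north
    for i in range(2 ** L - 1):
        (x, y), (hx, hy) = coords[i], headings[i]
        left_dir = (-hy, hx)
        right_dir = (hy, -hx)
        ln = seg[int(math.floor(math.log2(i + 1)))]
        for child, d in ((2 * i + 1, left_dir), (2 * i + 2, right_dir)):
            coords[child] = (x + ln * d[0], y + ln * d[1])
            headings[child] = d
    return coords


def _default_water_leaf(maze: MazeGraph) -> int:
    """Outer-ring leaf adjacent to a corner of the embedding."""
    xs = [abs(c[0]) for n, c in maze.cell_coords.items() if maze.is_leaf(n)]
    m = max(xs)
    for leaf in maze.leaves:
        x, y = maze.cell_coords[leaf]
        if x == m and y == m - 2:  # sibling of the (m, m) corner leaf
            return leaf
    return maze.leaves[-1]  # pragma: no cover - tiny mazes


# ---------------------------------------------------------------------
# turn sequences and symmetry maps
# ---------------------------------------------------------------------

def leaf_to_turns(maze: MazeGraph, node: int) -> Tuple[str, ...]:
    """Turn sequence (root to *node*) addressing any node; empty for root."""
    maze._check(node)
    turns: List[str] = []
    while node != 0:
        turns.append(LEFT if node % 2 == 1 else RIGHT)
        node = (node - 1) // 2
    return tuple(reversed(turns))


def turns_to_leaf(maze: MazeGraph, turns: Sequence[str]) -> int:
    """Node id addressed by a turn sequence from the root."""
    node = 0
    for t in turns:
        if t not in (LEFT, RIGHT):
            raise MazeError(f"invalid turn {t!r}")
        node = 2 * node + (1 if t == LEFT else 2)
    maze._check(node)
    return node


def _flip(turn: str) -> str:
    return RIGHT if turn == LEFT else LEFT


def image_node(maze: MazeGraph, leaf: int) -> int:
    """End node related to *leaf* by 180-degree rotation of the maze.

    Equivalently: same turn sequence with only the first turn flipped —
    the destination of an otherwise perfect path with a single mistake at
    the first T-junction.
    """
    if not maze.is_leaf(leaf):
        raise MazeError(f"image_node requires an end node, got {leaf}")
    turns = leaf_to_turns(maze, leaf)
    return turns_to_leaf(maze, (_flip(turns[0]),) + turns[1:])


def mirror_node(maze: MazeGraph, leaf: int) -> int:
    """End node related to *leaf* by the mirror symmetry (all turns flipped)."""
    if not maze.is_leaf(leaf):
        raise MazeError(f"mirror_node requires an end node, got {leaf}")
    return turns_to_leaf(maze, tuple(_flip(t) for t in leaf_to_turns(maze, leaf)))


def control_nodes(maze: MazeGraph, target: int) -> set[int]:
    """The three end nodes symmetry-related to *target* (target excluded).

    The maps are: flip the first turn (rotation image), flip every turn
    (mirror), and both.  Together with the identity they form a group of
    order 4 acting on the leaves without fixed points.
    """
    if not maze.is_leaf(target):
        raise MazeError(f"control_nodes requires an end node, got {target}")
    rot = image_node(maze, target)
    mir = mirror_node(maze, target)
    both = image_node(maze, mir)
    return {rot, mir, both}


def tree_distance(maze: MazeGraph, a: int, b: int) -> int:
    """Number of steps (edges) on the unique path between two nodes."""
    maze._check(a)
    maze._check(b)
    la, lb = maze.level[a], maze.level[b]
    x, y = a, b
    dist = 0
    while maze.level[x] > maze.level[y]:
        x = (x - 1) // 2
        dist += 1
    while maze.level[y] > maze.level[x]:
        y = (y - 1) // 2
        dist += 1
    while x != y:
        x = (x - 1) // 2
        y = (y - 1) // 2
        dist += 2
    return dist


def shortest_path(maze: MazeGraph, a: int, b: int) -> List[int]:
    """The unique node path from *a* to *b* (inclusive)."""
    maze._check(a)
    maze._check(b)
    up_a: List[int] = [a]
    up_b: List[int] = [b]
    x, y = a, b
    while maze.level[x] > maze.level[y]:
        x = (x - 1) // 2
        up_a.append(x)
    while maze.level[y] > maze.level[x]:
        y = (y - 1) // 2
        up_b.append(y)
    while x != y:
        x = (x - 1) // 2
        y = (y - 1) // 2
        up_a.append(x)
        up_b.append(y)
    return up_a + up_b[-2::-1]


# ---------------------------------------------------------------------
# ring classification
# ---------------------------------------------------------------------

def classify_rings(maze: MazeGraph) -> Dict[int, str]:
    """Label each end node outer / middle / inner by its embedded cell.

    Outer = leaves on the bounding perimeter of the leaf lattice (28 for
    the 6-level maze: 26 plus the water port and its neighbor); inner =
    the innermost block (16); the remaining leaves are middle.
    """
    if not maze.cell_coords:
        raise MazeError("embedding coordinates not populated")
    leaves = maze.leaves
    xs = sorted({maze.cell_coords[n][0] for n in leaves})
    side = len({abs(x) for x in xs} | {abs(maze.cell_coords[n][1]) for n in leaves})
    outer_r = max(abs(v) for n in leaves for v in maze.cell_coords[n])
    # innermost quarter of the lattice (central block half the side length)
    inner_r = sorted({abs(v) for n in leaves for v in maze.cell_coords[n]})[
        max(0, side // 2 - 1)
    ]
    rings: Dict[int, str] = {}
    for n in leaves:
        x, y = maze.cell_coords[n]
        if abs(x) == outer_r or abs(y) == outer_r:
            rings[n] = "outer"
        elif abs(x) <= inner_r and abs(y) <= inner_r:
            rings[n] = "inner"
        else:
            rings[n] = "middle"
    return rings


# ---------------------------------------------------------------------
# task complexity
# ---------------------------------------------------------------------

def decision_complexity_bits(n_junctions: int) -> float:
    """Complexity of mapping *n_junctions* three-way decisions, in bits.

    Each junction requires choosing one of three corridors, log2(3) bits.
    The entrance-to-port path of the 6-level maze crosses 6 junctions
    (9.5 bits); knowing the correct turn at all 63 junctions is 100 bits.
    """
    return n_junctions * math.log2(3.0)


def level_to_reporting(level: int) -> int:
    """Relabel an internal 0-based junction level to the 1-based figure
    convention in which end nodes of the 6-level maze sit at level 7."""
    return level + 1
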