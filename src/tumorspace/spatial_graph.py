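"""Finite-element spatial graphs for the birth-death dynamics.

A tumour grows on a graph embedded in ``R^D``: either a regular 2D/3D
lattice with nearest-neighbour adjacency, or an arbitrary point cloud in
which two points interact iff their Euclidean distance is strictly smaller
than an interaction range ``J``.  Each node is empty (state 0) or occupied
by a cell of subpopulation ``i >= 1``; occupied nodes additionally carry the
unique label of the resident cell.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SpatialGraph", "build_lattice", "build_graph_from_points"]


@dataclass
class SpatialGraph:
    """Spatial graph with per-node occupancy state.

    Attributes
    ----------
    coords : (N, D) float array of node coordinates.
    neighbors : list of int arrays; ``neighbors[i]`` are the nodes adjacent
        to node ``i``.  Adjacency is symmetric and irreflexive.
    state : (N,) int array; 0 = empty, ``i >= 1`` = subpopulation id of the
        occupying cell.
    cell_label : (N,) int array; 0 = no cell, otherwise the unique label of
        the cell occupying the node.
    interaction_range : the range ``J`` (point-cloud mode) or None (lattice).
    """

    coords: np.ndarray
    neighbors: list
    interaction_range: float | None = None
    state: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_label: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.coords)
        if self.state is None:
            self.state = np.zeros(n, dtype=np.int64)
        if self.cell_label is None:
            self.cell_label = np.zeros(n, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def dimension(self) -> int:
        return self.coords.shape[1]

    def degree(self, i: int) -> int:
        return len(self.neighbors[i])

    def occupied_nodes(self) -> np.ndarray:
        return np.nonzero(self.state)[0]

    def central_node(self) -> int:
        """Node closest to the coordinate centroid.

        Used as the default seeding position for the initial cell.  On the
        symmetric lattices used throughout, this coincides with the node of
        minimum total distance to all other nodes, while costing O(N).
        """
        centroid = self.coords.mean(axis=0)
        return int(np.argmin(((self.coords - centroid) ** 2).sum(axis=1)))

    def copy_empty(self) -> "SpatialGraph":
        """A copy sharing geometry but with all nodes empty."""
        return SpatialGraph(
            coords=self.coords,
            neighbors=self.neighbors,
            interaction_range=self.interaction_range,
        )

    def write_snapshot(self, path, time: float = 0.0) -> None:
        """Per-node CSV snapshot: node id, coordinates, state, label, time."""
        dim = self.dimension
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["node_id"]
                + [f"x{k}" for k in range(dim)]
                + ["state", "cell_label", "time"]
            )
            for i in range(self.n_nodes):
                writer.writerow(
                    [i]
                    + [f"{c:g}" for c in self.coords[i]]
                    + [int(self.state[i]), int(self.cell_label[i]), f"{time:g}"]
                )


def build_lattice(side_lengths, neighborhood: str = "von_neumann") -> SpatialGraph:
    """Build a regular 2D/3D lattice with unit spacing and hard walls.

    Parameters
    ----------
    side_lengths : sequence of 2 or 3 integers, each >= 2.
    neighborhood : "von_neumann" (4 neighbours in 2D, 6 in 3D; default) or
        "moore" (8 in 2D, 26 in 3D).

    Node indexing is 0-based row-major (C order) over the grid, so runs are
    reproducible across machines for a fixed seed.
    """
    sides = tuple(int(s) for s in side_lengths)
    d = len(sides)
    if d not in (2, 3):
        raise ValueError(f"lattice dimension must be 2 or 3, got {d}")
    if any(s < 2 for s in sides):
        raise ValueError(f"all side lengths must be >= 2, got {sides}")
    if neighborhood not in ("von_neumann", "moore"):
        raise ValueError(f"unknown neighborhood {neighborhood!r}")

    grids = np.meshgrid(*[np.arange(s) for s in sides], indexing="ij")
    coords = np.stack([g.ravel(order="C") for g in grids], axis=1).astype(float)

    # offsets defining the neighbourhood stencil
    if neighborhood == "von_neumann":
        offsets = []
        for axis in range(d):
            for delta in (-1, 1):
                off = [0] * d
                off[axis] = delta
                offsets.append(tuple(off))
    else:
        from itertools import product

        offsets = [o for o in product((-1, 0, 1), repeat=d) if any(o)]

    strides = np.array([int(np.prod(sides[k + 1:])) for k in range(d)])
    idx_grid = coords.astype(int)
    neighbors = []
    for i in range(len(coords)):
        pos = idx_grid[i]
        nbrs = []
        for off in offsets:
            q = pos + np.asarray(off)
            if np.all(q >= 0) and np.all(q < sides):
                nbrs.append(int(q @ strides))
        neighbors.append(np.array(sorted(nbrs), dtype=np.int64))
    return SpatialGraph(coords=coords, neighbors=neighbors)


def build_graph_from_points(points, J: float) -> SpatialGraph:
    """Build a graph from a point cloud: i ~ j iff ||p_i - p_j|| < J.

    The inequality is strict: a pair at distance exactly ``J`` is NOT
    connected.  Duplicate coordinates are allowed (distance 0 < J implies
    they are connected) but trigger a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 1:
        raise ValueError("points must be a non-empty (N, D) array")
    if not J > 0:
        raise ValueError(f"interaction range J must be positive, got {J}")

    tree = cKDTree(pts)
    if len(tree.query_pairs(r=0.0)) > 0:
        warnings.warn("duplicate coordinates found; coincident points are connected")

    neighbors: list[list[int]] = [[] for _ in range(len(pts))]
    for i, j in tree.query_pairs(r=J):  # query_pairs uses <=; enforce <
        if np.linalg.norm(pts[i] - pts[j]) < J:
            neighbors[i].append(j)
            neighbors[j].append(i)
    return SpatialGraph(
        coords=pts,
        neighbors=[np.array(sorted(ns), dtype=np.int64) for ns in neighbors],
        interaction_range=float(J),
    )
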