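"""Polygon contiguity graphs and self-included, row-standardized weights.

Queen contiguity links two polygons whose boundaries share at least one
point (edge or corner); rook contiguity requires a shared boundary segment
of positive length.  Candidate pairs are pre-filtered with an STR-tree so
adjacency detection scales far below the naive O(N^2) pairwise test, which
remains the correctness oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Union

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .errors import DuplicateIdError, InvalidGeometryError

Mode = Literal["queen", "rook"]

_POLYGONAL = ("Polygon", "MultiPolygon")


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetric, irreflexive adjacency lists for a polygon set.

    Self-inclusion is deliberately *not* part of the graph: it is applied at
    weighting time by :func:`row_standardize_with_self`, so that neighbor
    counts stay unambiguous.

    Parameters
    ----------
    mode : {"queen", "rook"}
        Contiguity rule the graph was built under.
    neighbors : mapping of id -> frozenset of ids
        Adjacency lists; every id in the polygon set is a key, including
        islands (empty set).  Self is excluded.
    snap_tolerance : float
        Vertex-snapping distance applied before adjacency testing.
    """

    mode: Mode
    neighbors: Mapping[str, frozenset]
    snap_tolerance: float = 0.0

    def __post_init__(self):
        for i, js in self.neighbors.items():
            if i in js:
                raise ValueError(f"graph is reflexive at {i!r}")
            for j in js:
                if i not in self.neighbors.get(j, ()):
                    raise ValueError(f"graph is asymmetric: {i!r} -> {j!r}")

    def __len__(self) -> int:
        return len(self.neighbors)

    def neighbor_counts(self) -> dict:
        """Per-id neighbor count, self excluded."""
        return {i: len(js) for i, js in self.neighbors.items()}

    def restricted_to(self, keep: Iterable) -> "NeighborGraph":
        """Induced subgraph on ``keep`` (ids not in the graph are ignored)."""
        keep = frozenset(keep)
        return NeighborGraph(
            mode=self.mode,
            neighbors={
                i: self.neighbors[i] & keep for i in self.neighbors if i in keep
            },
            snap_tolerance=self.snap_tolerance,
        )


@dataclass(frozen=True)
class WeightsRow:
    """Self-included, row-standardized weights for one focal tract.

    All weights are equal to ``1 / (n_neigh + 1)`` and sum to one; the focal
    tract itself is one of the keys.
    """

    focal: str
    weights: Mapping[str, float]

    @property
    def n_neigh(self) -> int:
        """Number of neighbors, the self-included focal excluded."""
        return len(self.weights) - 1

    @property
    def W_i(self) -> float:
        """Row sum of weights (1.0 after row-standardization)."""
        return float(sum(self.weights.values()))

    @property
    def S1_i(self) -> float:
        """Sum of squared weights."""
        return float(sum(w * w for w in self.weights.values()))


def _as_items(polygons: Union[Mapping, Iterable]) -> list:
    if isinstance(polygons, Mapping):
        return list(polygons.items())
    items = list(polygons)
    seen = set()
    for uid, _ in items:
        if uid in seen:
            raise DuplicateIdError(uid)
        seen.add(uid)
    return items


def build_neighbor_graph(
    polygons: Union[Mapping, Iterable],
    mode: Mode = "queen",
    snap_tolerance: float = 0.0,
) -> NeighborGraph:
    """Detect polygon adjacency under queen or rook contiguity.

    Parameters
    ----------
    polygons : mapping id -> shapely geometry, or iterable of (id, geometry)
        Valid planar polygonal geometries in a common coordinate system.
    mode : {"queen", "rook"}
        Queen links any two polygons whose boundaries intersect in at least
        one point; rook links only pairs whose shared boundary has length
        strictly greater than ``snap_tolerance``.
    snap_tolerance : float
        If positive, vertices are snapped to a grid of this size before
        testing, so near-coincident boundaries register as touching.

    Returns
    -------
    NeighborGraph

    Raises
    ------
    InvalidGeometryError
        For a missing, empty, non-polygonal or self-intersecting geometry
        (the offending id is reported).
    DuplicateIdError
        If an id occurs twice (only possible for pair-iterable input).
    ValueError
        For an unknown mode or negative tolerance.
    """
    if mode not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity mode {mode!r}")
    if snap_tolerance < 0:
        raise ValueError("snap_tolerance must be >= 0")

    items = _as_items(polygons)
    ids = [uid for uid, _ in items]
    for uid, geom in items:
        if geom is None or not isinstance(geom, BaseGeometry) or geom.is_empty:
            raise InvalidGeometryError(uid, "empty or missing geometry")
        if geom.geom_type not in _POLYGONAL:
            raise InvalidGeometryError(uid, f"not polygonal ({geom.geom_type})")
        if not geom.is_valid:
            raise InvalidGeometryError(uid, "invalid (self-intersecting?) geometry")

    geoms = np.array([geom for _, geom in items], dtype=object)
    if snap_tolerance > 0:
        geoms = shapely.set_precision(geoms, snap_tolerance)

    neighbors = {uid: set() for uid in ids}
    if len(ids) > 1:
        tree = STRtree(geoms)
        left, right = tree.query(geoms, predicate="intersects")
        for i, j in zip(left.tolist(), right.tolist()):
            if i >= j:  # dedupe symmetric pairs, drop self hits
                continue
            if mode == "rook":
                shared = geoms[i].boundary.intersection(geoms[j].boundary)
                if shared.length <= snap_tolerance:
                    continue
            neighbors[ids[i]].add(ids[j])
            neighbors[ids[j]].add(ids[i])

    return NeighborGraph(
        mode=mode,
        neighbors={uid: frozenset(js) for uid, js in neighbors.items()},
        snap_tolerance=snap_tolerance,
    )


def row_standardize_with_self(graph: NeighborGraph) -> dict:
    """Turn adjacency lists into self-included, row-standardized weights.

    Each focal tract receives equal weights of ``1 / (n_neigh + 1)`` over
    itself and its neighbors; an island gets ``{self: 1.0}``.

    Returns
    -------
    dict of id -> WeightsRow
    """
    rows = {}
    for focal, js in graph.neighbors.items():
        members = [focal, *sorted(js)]
        w = 1.0 / len(members)
        rows[focal] = WeightsRow(focal=focal, weights={m: w for m in members})
    return rows
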