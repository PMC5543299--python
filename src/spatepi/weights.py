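"""Spatial adjacency (contiguity) weights and centroid distance matrices.

Areal analyses here consume adjacency as an explicit undirected edge list
rather than deriving it from polygon geometry; :func:`spatepi.io.geojson_to_edges`
can produce such an edge list from a polygon FeatureCollection. Higher-order
contiguity ("neighbours of neighbours", queen second order in the GIS sense)
is defined through shortest-path distance on the contiguity graph: the
order-``k`` neighbours of area *i* are the areas at graph distance exactly
``k``, optionally unioned with all lower orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import shortest_path


@dataclass(frozen=True)
class WeightsMatrix:
    """Symmetric binary contiguity weights.

    Attributes
    ----------
    area_ids : tuple
        Ordered area identifiers; row/column ``k`` of ``W`` belongs to
        ``area_ids[k]``.
    W : ndarray of shape (n, n)
        Binary symmetric matrix, zero diagonal. ``W[i, j] == 1`` iff the
        areas are neighbours at the requested contiguity order.
    order : int
        Contiguity order used to build the matrix.
    include_lower : bool
        Whether lower orders were unioned in.
    """

    area_ids: tuple
    W: np.ndarray
    order: int = 1
    include_lower: bool = True

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.array_equal(W, W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have a zero diagonal")
        object.__setattr__(self, "W", W.astype(np.int8, copy=False))

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def row_sums(self) -> np.ndarray:
        """Number of neighbours m_i per area."""
        return np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def islands(self) -> list:
        """Ids of areas with no neighbours."""
        rs = self.row_sums
        return [self.area_ids[i] for i in np.flatnonzero(rs == 0)]

    def index_of(self, area_id: Hashable) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise KeyError(f"unknown area id: {area_id!r}") from None

    def neighbors(self, area_id: Hashable) -> list:
        i = self.index_of(area_id)
        return [self.area_ids[j] for j in np.flatnonzero(self.W[i])]

    def to_sparse(self) -> sparse.csr_matrix:
        return sparse.csr_matrix(self.W)

    def edge_pairs(self) -> np.ndarray:
        """(n_edges, 2) index array with i < j, each undirected edge once."""
        iu, ju = np.nonzero(np.triu(self.W, k=1))
        return np.column_stack([iu, ju])

    def connected_component_labels(self) -> np.ndarray:
        from scipy.sparse.csgraph import connected_components

        _, labels = connected_components(self.to_sparse(), directed=False)
        return labels


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Euclidean centroid-distance matrix."""

    area_ids: tuple
    D: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
        if np.any(D < 0) or np.any(np.diag(D) != 0):
            raise ValueError("D must be nonnegative with zero diagonal")
        object.__setattr__(self, "D", D)

    @property
    def n(self) -> int:
        return len(self.area_ids)


def build_weights(
    edges: Iterable[tuple],
    area_ids: Sequence[Hashable],
    order: int = 1,
    include_lower: bool = True,
) -> WeightsMatrix:
    """Build a contiguity weights matrix from an undirected edge list.

    Parameters
    ----------
    edges : iterable of (id_a, id_b)
        Undirected adjacency; duplicates and reversed duplicates are ignored.
    area_ids : sequence
        The full ordered set of area identifiers (isolated areas allowed).
    order : int
        Contiguity order. ``order=1`` is the symmetrized input adjacency;
        ``order=k`` keeps pairs at shortest-path distance exactly ``k``.
    include_lower : bool
        Union all orders ``1..k`` (GeoDa's "include lower orders").

    Raises
    ------
    KeyError
        If an edge references an id not in ``area_ids``.
    ValueError
        For ``order < 1`` or a self-loop edge.
    """
    if order < 1:
        raise ValueError(f"contiguity order must be >= 1, got {order}")
    ids = tuple(area_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("area ids must be unique")
    pos = {a: k for k, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n), dtype=np.int8)
    for a, b in edges:
        if a not in pos:
            raise KeyError(f"unknown area id in edge list: {a!r}")
        if b not in pos:
            raise KeyError(f"unknown area id in edge list: {b!r}")
        if a == b:
            raise ValueError(f"self-loop edge for area {a!r}")
        A[pos[a], pos[b]] = 1
        A[pos[b], pos[a]] = 1
    if order == 1:
        return WeightsMatrix(ids, A, order=1, include_lower=include_lower)
    dist = shortest_path(sparse.csr_matrix(A), method="D", unweighted=True, directed=False)
    if include_lower:
        hit = (dist >= 1) & (dist <= order)
    else:
        hit = dist == order
    W = np.where(hit, 1, 0).astype(np.int8)
    np.fill_diagonal(W, 0)
    return WeightsMatrix(ids, W, order=order, include_lower=include_lower)


def pairwise_distances(areas: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance matrix between area centroids.

    ``areas`` needs columns ``id``, ``x``, ``y`` (planar coordinates).
    """
    from scipy.spatial.distance import pdist, squareform

    xy = areas[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        bad = areas["id"].iloc[np.flatnonzero(~np.isfinite(xy).all(axis=1))[0]]
        raise ValueError(f"non-finite centroid coordinate for area {bad!r}")
    if len(xy) == 1:
        D = np.zeros((1, 1))
    else:
        D = squareform(pdist(xy, metric="euclidean"))
    return DistanceMatrix(tuple(areas["id"]), D)
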