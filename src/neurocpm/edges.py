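"""Canonical edge indexing and signed edge masks.

Edges are unordered node pairs ``(i, j)`` with ``i < j`` over the strict upper
triangle of an ``N x N`` connectivity matrix, giving ``M = N (N - 1) / 2``
edges.  Edge index ``k`` enumerates pairs row by row, matching
``numpy.triu_indices(N, k=1)``.  A signed mask holds the positive network
(edges whose strength correlates positively with severity) and the negative
network as disjoint sets of edge indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs, M = N(N-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (i, j) of 0-based endpoints for every canonical edge, i < j."""
    return np.triu_indices(n_nodes, k=1)


def edge_index(i, j, n_nodes: int):
    """Canonical edge index of pair(s) (i, j); order of i, j is irrelevant."""
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i == j):
        raise ValueError("self-pairs (i == i) are not edges")
    if np.any((i < 0) | (j < 0) | (i >= n_nodes) | (j >= n_nodes)):
        raise ValueError("node index out of range")
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    k = lo * (2 * n_nodes - lo - 1) // 2 + (hi - lo - 1)
    return k if k.ndim else int(k)


def vectorize_matrix(z: np.ndarray) -> np.ndarray:
    """Upper-triangle edge vector (length M) of a square matrix."""
    n = z.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.asarray(z)[iu]


def matrix_from_edges(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Symmetric matrix with zero diagonal from an M-length edge vector."""
    z = np.zeros((n_nodes, n_nodes), dtype=float)
    iu = np.triu_indices(n_nodes, k=1)
    z[iu] = values
    z[(iu[1], iu[0])] = values
    return z


@dataclass(frozen=True)
class EdgeMask:
    """Disjoint positive and negative edge-index sets over one atlas.

    ``pos_edges``/``neg_edges`` are sorted arrays of canonical edge indices.
    """

    n_nodes: int
    pos_edges: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    neg_edges: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        pos = np.unique(np.asarray(self.pos_edges, dtype=np.int64))
        neg = np.unique(np.asarray(self.neg_edges, dtype=np.int64))
        m = n_edges(self.n_nodes)
        for name, arr in (("pos_edges", pos), ("neg_edges", neg)):
            if arr.size and (arr.min() < 0 or arr.max() >= m):
                raise ValueError(f"{name} contains edge indices outside [0, {m})")
        if np.intersect1d(pos, neg).size:
            raise ValueError("positive and negative edge sets must be disjoint")
        object.__setattr__(self, "pos_edges", pos)
        object.__setattr__(self, "neg_edges", neg)

    @property
    def n_pos(self) -> int:
        return int(self.pos_edges.size)

    @property
    def n_neg(self) -> int:
        return int(self.neg_edges.size)

    @property
    def is_empty(self) -> bool:
        return self.n_pos == 0 and self.n_neg == 0

    def sign_vector(self) -> np.ndarray:
        """Length-M int8 vector: +1 on positive edges, -1 on negative, else 0."""
        s = np.zeros(n_edges(self.n_nodes), dtype=np.int8)
        s[self.pos_edges] = 1
        s[self.neg_edges] = -1
        return s

    def all_edges(self) -> np.ndarray:
        return np.union1d(self.pos_edges, self.neg_edges)

    @classmethod
    def from_sign_vector(cls, signs: np.ndarray, n_nodes: int) -> "EdgeMask":
        signs = np.asarray(signs)
        if signs.shape != (n_edges(n_nodes),):
            raise ValueError("sign vector length must equal M = N(N-1)/2")
        return cls(n_nodes=n_nodes,
                   pos_edges=np.flatnonzero(signs > 0),
                   neg_edges=np.flatnonzero(signs < 0))

    @classmethod
    def from_pairs(cls, n_nodes: int,
                   pos_pairs=(), neg_pairs=()) -> "EdgeMask":
        """Build from 0-based (i, j) pairs; pairs are canonicalized."""
        def to_idx(pairs):
            if len(pairs) == 0:
                return np.empty(0, dtype=np.int64)
            arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
            return np.asarray(edge_index(arr[:, 0], arr[:, 1], n_nodes), dtype=np.int64)
        return cls(n_nodes=n_nodes, pos_edges=to_idx(pos_pairs), neg_edges=to_idx(neg_pairs))
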