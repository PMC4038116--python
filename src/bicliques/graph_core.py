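"""Bipartite and general graph data model.

A :class:`BipartiteGraph` holds two labeled vertex partitions — *left*
(conventionally ``U``, size ``m``) and *right* (``V``, size ``n``) — and a
set of cross-partition edges.  Adjacency is stored as fixed-width bitmaps
(arbitrary-precision integers, one per vertex), so neighborhood
intersections and popcounts used throughout the enumeration inner loop are
single machine-assisted operations.

A :class:`Biclique` is a pair of non-empty vertex subsets inducing a
complete bipartite subgraph; equality and hashing are set-based so that a
biclique is the same object regardless of member ordering.

:func:`inflate` converts a bipartite graph into a general graph by adding
every intra-partition edge, turning maximal bicliques into maximal cliques.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Sequence

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

Label = Hashable


def _pack_mask(bits: np.ndarray) -> int:
    """Pack a boolean vector into an integer bitmap (bit i = bits[i])."""
    return int.from_bytes(
        np.packbits(bits.astype(np.uint8), bitorder="little").tobytes(), "little"
    )


def _mask_indices(mask: int) -> Iterator[int]:
    """Yield set-bit positions of an integer bitmap in increasing order."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


class BipartiteGraph:
    """Two labeled vertex partitions with cross-partition edges only.

    Parameters
    ----------
    left_labels, right_labels:
        Ordered sequences of distinct labels.  The same label string may
        appear in both partitions; it denotes two distinct vertices.
    edges:
        Iterable of ``(left_label, right_label)`` pairs.  Duplicates are
        deduplicated with a logged warning.
    """

    def __init__(
        self,
        left_labels: Sequence[Label],
        right_labels: Sequence[Label],
        edges: Iterable[tuple[Label, Label]] = (),
    ):
        self.left_labels: tuple[Label, ...] = tuple(left_labels)
        self.right_labels: tuple[Label, ...] = tuple(right_labels)
        self._left_index = {lab: i for i, lab in enumerate(self.left_labels)}
        self._right_index = {lab: j for j, lab in enumerate(self.right_labels)}
        if len(self._left_index) != len(self.left_labels):
            raise InputError("duplicate labels in left partition")
        if len(self._right_index) != len(self.right_labels):
            raise InputError("duplicate labels in right partition")

        # bit i of _adj_right[j] set iff (left i, right j) is an edge
        self._adj_right: list[int] = [0] * len(self.right_labels)
        self._adj_left: list[int] = [0] * len(self.left_labels)
        n_edges = 0
        n_dup = 0
        for u, v in edges:
            i = self._left_index.get(u)
            j = self._right_index.get(v)
            if i is None:
                raise InputError(f"edge endpoint {u!r} not in left partition")
            if j is None:
                raise InputError(f"edge endpoint {v!r} not in right partition")
            bit = 1 << i
            if self._adj_right[j] & bit:
                n_dup += 1
                continue
            self._adj_right[j] |= bit
            self._adj_left[i] |= 1 << j
            n_edges += 1
        if n_dup:
            logger.warning("deduplicated %d duplicate edge(s)", n_dup)
        self._n_edges = n_edges

    @classmethod
    def from_biadjacency(
        cls,
        left_labels: Sequence[Label],
        right_labels: Sequence[Label],
        biadjacency: np.ndarray,
    ) -> "BipartiteGraph":
        """Build from a dense boolean biadjacency matrix of shape (m, n)."""
        B = np.asarray(biadjacency, dtype=bool)
        if B.shape != (len(left_labels), len(right_labels)):
            raise InputError(
                f"biadjacency shape {B.shape} does not match label counts "
                f"({len(left_labels)}, {len(right_labels)})"
            )
        g = cls(left_labels, right_labels)
        g._adj_right = [_pack_mask(B[:, j]) for j in range(B.shape[1])]
        g._adj_left = [_pack_mask(B[i, :]) for i in range(B.shape[0])]
        g._n_edges = int(B.sum())
        return g

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[Label, Label]]) -> "BipartiteGraph":
        """Build from edges alone; vertices appear in first-encounter order."""
        edges = list(edges)
        left: dict[Label, None] = {}
        right: dict[Label, None] = {}
        for u, v in edges:
            left.setdefault(u)
            right.setdefault(v)
        return cls(tuple(left), tuple(right), edges)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_left(self) -> int:
        return len(self.left_labels)

    @property
    def n_right(self) -> int:
        return len(self.right_labels)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BipartiteGraph(m={self.n_left}, n={self.n_right}, e={self.n_edges})"
        )

    def left_index(self, label: Label) -> int:
        try:
            return self._left_index[label]
        except KeyError:
            raise InputError(f"unknown left vertex {label!r}") from None

    def right_index(self, label: Label) -> int:
        try:
            return self._right_index[label]
        except KeyError:
            raise InputError(f"unknown right vertex {label!r}") from None

    def has_edge(self, u: Label, v: Label) -> bool:
        return bool(self._adj_right[self.right_index(v)] >> self.left_index(u) & 1)

    def neighbors_of_right(self, v: Label) -> frozenset[Label]:
        """Left-partition neighbors N(v) of a right vertex."""
        mask = self._adj_right[self.right_index(v)]
        return frozenset(self.left_labels[i] for i in _mask_indices(mask))

    def neighbors_of_left(self, u: Label) -> frozenset[Label]:
        """Right-partition neighbors N(u) of a left vertex."""
        mask = self._adj_left[self.left_index(u)]
        return frozenset(self.right_labels[j] for j in _mask_indices(mask))

    def edges(self) -> Iterator[tuple[Label, Label]]:
        """Iterate edges in left-major, partition-order: deterministic."""
        for i, u in enumerate(self.left_labels):
            for j in _mask_indices(self._adj_left[i]):
                yield u, self.right_labels[j]

    def transpose(self) -> "BipartiteGraph":
        """Swap the two partitions (left becomes right and vice versa)."""
        g = BipartiteGraph(self.right_labels, self.left_labels)
        g._adj_right = list(self._adj_left)
        g._adj_left = list(self._adj_right)
        g._n_edges = self._n_edges
        return g

    # -- label/mask conversions used by the enumeration machinery ----------

    def left_mask_to_labels(self, mask: int) -> tuple[Label, ...]:
        return tuple(self.left_labels[i] for i in _mask_indices(mask))

    def right_mask_to_labels(self, mask: int) -> tuple[Label, ...]:
        return tuple(self.right_labels[j] for j in _mask_indices(mask))

    def right_subset_mask(self, labels: Iterable[Label]) -> int:
        mask = 0
        for v in labels:
            mask |= 1 << self.right_index(v)
        return mask

    def left_subset_mask(self, labels: Iterable[Label]) -> int:
        mask = 0
        for u in labels:
            mask |= 1 << self.left_index(u)
        return mask


@dataclass(frozen=True)
class Biclique:
    """A complete bipartite subgraph: non-empty ``left`` x ``right``.

    Stored in canonical form (members sorted by the host graph's partition
    order when built through :meth:`from_sets`); equality and hashing
    compare the member *sets*, so ordering never affects identity.
    """

    left: tuple[Label, ...]
    right: tuple[Label, ...]

    def __post_init__(self):
        if not self.left or not self.right:
            raise InputError("biclique sides must be non-empty")

    @classmethod
    def from_sets(
        cls, g: BipartiteGraph, left: Iterable[Label], right: Iterable[Label]
    ) -> "Biclique":
        """Canonicalize subsets of a host graph by its partition order."""
        li = sorted(g.left_index(u) for u in set(left))
        ri = sorted(g.right_index(v) for v in set(right))
        return cls(
            tuple(g.left_labels[i] for i in li),
            tuple(g.right_labels[j] for j in ri),
        )

    @property
    def left_set(self) -> frozenset[Label]:
        return frozenset(self.left)

    @property
    def right_set(self) -> frozenset[Label]:
        return frozenset(self.right)

    @property
    def n_left(self) -> int:
        return len(self.left)

    @property
    def n_right(self) -> int:
        return len(self.right)

    @property
    def n_vertices(self) -> int:
        return len(self.left) + len(self.right)

    @property
    def n_edges(self) -> int:
        return len(self.left) * len(self.right)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Biclique):
            return NotImplemented
        return (
            frozenset(self.left) == frozenset(other.left)
            and frozenset(self.right) == frozenset(other.right)
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.left), frozenset(self.right)))

    def is_complete_in(self, g: BipartiteGraph) -> bool:
        """True iff every cross pair of this biclique is an edge of ``g``."""
        lmask = g.left_subset_mask(self.left)
        return all(
            g._adj_right[g.right_index(v)] & lmask == lmask for v in self.right
        )


@dataclass(frozen=True)
class GeneralGraph:
    """Undirected simple graph: labels plus a symmetric, irreflexive edge set."""

    labels: tuple[Label, ...]
    edge_set: frozenset[frozenset[Label]] = field(default_factory=frozenset)

    def __post_init__(self):
        index = set(self.labels)
        if len(index) != len(self.labels):
            raise InputError("duplicate vertex labels")
        for e in self.edge_set:
            if len(e) != 2:
                raise InputError(f"self-loop or malformed edge {set(e)!r}")
            if not e <= index:
                raise InputError(f"edge {set(e)!r} references unknown vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edge_set)

    def has_edge(self, a: Label, b: Label) -> bool:
        return frozenset((a, b)) in self.edge_set

    def neighbors(self, a: Label) -> frozenset[Label]:
        return frozenset(
            next(iter(e - {a})) for e in self.edge_set if a in e
        )

    def density(self) -> float:
        n = self.n_vertices
        if n < 2:
            raise InputError("density undefined for graphs with fewer than 2 vertices")
        return self.n_edges / (n * (n - 1) / 2)


# -- module-level operations ----------------------------------------------


def common_neighbors(g: BipartiteGraph, right_subset: Iterable[Label]) -> set[Label]:
    """Left vertices adjacent to *every* member of ``right_subset``.

    The empty subset returns all of the left partition (the empty
    intersection convention, needed so the enumeration root has L = U).
    """
    mask = (1 << g.n_left) - 1
    for v in right_subset:
        mask &= g._adj_right[g.right_index(v)]
    return set(g.left_mask_to_labels(mask))


def density(g: BipartiteGraph) -> float:
    """Edge density e / (m * n); undefined when either partition is empty."""
    if g.n_left == 0 or g.n_right == 0:
        raise InputError("density undefined for an empty partition")
    return g.n_edges / (g.n_left * g.n_right)


def inflate(g: BipartiteGraph) -> GeneralGraph:
    """Clique inflation: add every intra-partition edge.

    Maximal bicliques of ``g`` with both sides non-empty become maximal
    cliques of the result that span both partitions.  Labels are prefixed
    "L:"/"R:" so partitions sharing a label string never collide.  The
    result has ``e + m(m-1)/2 + n(n-1)/2`` edges.
    """
    left = tuple(f"L:{u}" for u in g.left_labels)
    right = tuple(f"R:{v}" for v in g.right_labels)
    edges: set[frozenset[Label]] = {
        frozenset((f"L:{u}", f"R:{v}")) for u, v in g.edges()
    }
    for part in (left, right):
        for a_i in range(len(part)):
            for b_i in range(a_i + 1, len(part)):
                edges.add(frozenset((part[a_i], part[b_i])))
    return GeneralGraph(left + right, frozenset(edges))
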