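"""Maximal biclique enumeration: MBEA and its improved variant iMBEA.

Both algorithms perform a depth-first branch-and-bound traversal over
subsets of one partition (the *enumeration side*, by default the smaller
one).  Each search node carries four sets:

``R``  the current biclique seed (enumeration-side vertices),
``L``  the common neighbors of R on the other side,
``P``  candidates that may still extend R,
``Q``  former candidates, used to detect non-maximality.

Expanding a candidate ``x`` forms ``L' = L ∩ N(x)`` and ``R' = R ∪ {x}``.
If any former candidate is adjacent to all of L' the whole branch can only
produce non-maximal bicliques and is pruned.  Otherwise candidates adjacent
to all of L' (the set ``S``) are absorbed into R' — (L', R' ∪ S) is then a
maximal biclique and is emitted — and the search recurses on the remaining
candidates with a positive but incomplete neighborhood in L'.

iMBEA adds two refinements: candidates are processed in non-decreasing
order of common-neighborhood size |N_L(v)| (re-ranked at every node), and
absorbed vertices whose neighborhood within L equals that of ``x`` are
retired to Q on return instead of being re-expanded, since any biclique
containing them without x is dominated.

The traversal uses an explicit stack, so search depth is bounded only by
memory, never by the interpreter recursion limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .errors import ContractError, InputError
from .graph_core import Biclique, BipartiteGraph, Label

ALGORITHMS = ("mbea", "imbea")
SIDES = ("auto", "left", "right")


@dataclass
class SearchState:
    """The dynamic 4-tuple of one search node, at the label level.

    Invariants: P, Q, R pairwise disjoint; P ∪ Q = vertices outside R with
    at least one neighbor in L; L = common neighbors of R (all of the
    non-enumerated side when R is empty).  ``L`` and ``R`` are reported in
    the emitted biclique; ``P`` keeps candidate order; ``Q`` is unordered.
    """

    graph: BipartiteGraph
    L: frozenset[Label]
    R: frozenset[Label]
    P: list[Label]
    Q: frozenset[Label]


@dataclass
class ExpansionRecord:
    """Outcome of expanding candidate ``x`` from a search node.

    ``S`` are candidates absorbed into the new seed (adjacent to all of
    L'); ``S_eq`` the subset of S whose neighborhood within the *parent* L
    equals that of x (retired under iMBEA); ``T`` the former candidates
    adjacent to all of L' — non-empty T proves every biclique in the
    subtree non-maximal.
    """

    x: Label
    L_new: frozenset[Label]
    R_new: frozenset[Label]
    P_new: list[Label]
    Q_new: frozenset[Label]
    S: frozenset[Label]
    S_eq: frozenset[Label]
    T: frozenset[Label]

    @property
    def is_maximal(self) -> bool:
        return not self.T


@dataclass
class EnumerationResult:
    """Emitted bicliques (when collected) plus recursion-tree statistics."""

    bicliques: list[Biclique] | None
    count: int
    nodes: int
    leaves_pruned: int
    max_depth: int
    algorithm: str
    side: str

    def __iter__(self):
        if self.bicliques is None:
            raise ContractError("bicliques were streamed, not collected")
        return iter(self.bicliques)


def select_candidate(state: SearchState, algorithm: str = "imbea") -> Label:
    """Choose the next candidate from P.

    mbea takes the first candidate in list order; imbea the candidate with
    the smallest common neighborhood |N_L(v)|, ties broken stably by list
    order.
    """
    if algorithm not in ALGORITHMS:
        raise InputError(f"unknown algorithm {algorithm!r}")
    if not state.P:
        raise ContractError("select_candidate requires a non-empty candidate set")
    if algorithm == "mbea":
        return state.P[0]
    g = state.graph
    lmask = g.left_subset_mask(state.L)
    return min(
        state.P, key=lambda v: (g._adj_right[g.right_index(v)] & lmask).bit_count()
    )


def expand_step(state: SearchState, x: Label) -> ExpansionRecord:
    """Apply the extension step for candidate ``x`` at the label level.

    Reference form of one recursion-tree node, mirrored by the bitmap
    engine in :func:`enumerate_maximal_bicliques`; used for inspection and
    for testing the recursion contract directly.
    """
    g = state.graph
    if x not in state.P:
        raise ContractError(f"{x!r} is not a candidate")
    lmask = g.left_subset_mask(state.L)
    l_new = lmask & g._adj_right[g.right_index(x)]
    size_l = l_new.bit_count()

    def nl(v: Label) -> int:
        return g._adj_right[g.right_index(v)] & l_new

    T = frozenset(v for v in state.Q if nl(v) == l_new)
    Q_new = frozenset(v for v in state.Q if nl(v))
    S, P_new = [], []
    for v in state.P:
        if v == x:
            continue
        nv = nl(v)
        if nv == l_new:
            S.append(v)
        elif 0 < nv.bit_count() < size_l:
            P_new.append(v)
    nx_parent = g._adj_right[g.right_index(x)] & lmask
    S_eq = frozenset(
        v for v in S if g._adj_right[g.right_index(v)] & lmask == nx_parent
    )
    return ExpansionRecord(
        x=x,
        L_new=frozenset(g.left_mask_to_labels(l_new)),
        R_new=state.R | {x} | set(S),
        P_new=P_new,
        Q_new=Q_new,
        S=frozenset(S),
        S_eq=S_eq,
        T=T,
    )


@dataclass
class _Frame:
    L: int                       # bitmap over the non-enumerated side
    R: tuple[int, ...]           # enumeration-side indices in the seed
    P: list[int]                 # candidate indices, in processing order
    Q: list[int]                 # former candidate indices
    pending: tuple[int, list[int]] | None = None  # (x, S_eq) of an open child


def _run(
    adj: Sequence[int],
    n_left: int,
    order: Sequence[int],
    algorithm: str,
    emit: Callable[[int, tuple[int, ...]], None],
) -> tuple[int, int, int]:
    """Bitmap engine.  ``adj[j]`` is the left-side bitmap of right vertex j.

    Emits ``(L_mask, R_indices)`` pairs; returns (nodes, leaves_pruned,
    max_depth).  The root node is counted; every candidate expansion is one
    further node.
    """
    imbea = algorithm == "imbea"
    P0 = [v for v in order if adj[v]]
    if imbea:
        P0.sort(key=lambda v: adj[v].bit_count())  # stable: ties keep order
    full = (1 << n_left) - 1
    nodes, pruned, max_depth = 1, 0, 0
    if not P0:
        return nodes, pruned, max_depth
    stack = [_Frame(L=full, R=(), P=P0, Q=[])]

    def retire(f: _Frame, x: int, s_eq: list[int]) -> None:
        f.P.remove(x)
        f.Q.append(x)
        for v in s_eq:
            f.P.remove(v)
            f.Q.append(v)

    while stack:
        f = stack[-1]
        if f.pending is not None:
            x, s_eq = f.pending
            f.pending = None
            retire(f, x, s_eq)
        if not f.P:
            stack.pop()
            continue

        x = f.P[0]
        nodes += 1
        max_depth = max(max_depth, len(stack))
        L1 = f.L & adj[x]
        # Former candidates adjacent to all of L' prune the branch.
        Q1: list[int] = []
        pruned_here = False
        for v in f.Q:
            nv = adj[v] & L1
            if nv == L1:
                pruned_here = True
                break
            if nv:
                Q1.append(v)
        if pruned_here:
            pruned += 1
            retire(f, x, [])
            continue

        size_l = L1.bit_count()
        S: list[int] = []
        P1: list[int] = []
        for v in f.P:
            if v == x:
                continue
            nv = adj[v] & L1
            if nv == L1:
                S.append(v)
            elif 0 < nv.bit_count() < size_l:
                P1.append(v)
        R1 = f.R + (x,) + tuple(S)
        emit(L1, R1)
        if imbea:
            nx = adj[x] & f.L
            s_eq = [v for v in S if adj[v] & f.L == nx]
        else:
            s_eq = []
        if P1:
            if imbea:
                P1.sort(key=lambda v: (adj[v] & L1).bit_count())
            f.pending = (x, s_eq)
            stack.append(_Frame(L=L1, R=R1, P=P1, Q=Q1))
        else:
            retire(f, x, s_eq)
    return nodes, pruned, max_depth


def enumerate_maximal_bicliques(
    g: BipartiteGraph,
    algorithm: str = "imbea",
    side: str = "auto",
    emit: Callable[[Biclique], None] | None = None,
) -> EnumerationResult:
    """Enumerate every maximal biclique of ``g`` with both sides non-empty.

    Each maximal biclique is produced exactly once, in a deterministic
    depth-first order fixed by the input order and the algorithm variant.
    With ``emit`` given, bicliques are streamed to the consumer and not
    retained; otherwise they are collected on the result.

    ``side`` picks the partition whose subsets are explored: ``auto`` uses
    the smaller partition, ``left``/``right`` force one.
    """
    if algorithm not in ALGORITHMS:
        raise InputError(f"unknown algorithm {algorithm!r}")
    if side not in SIDES:
        raise InputError(f"unknown side {side!r}")
    enum_side = side
    if side == "auto":
        enum_side = "right" if g.n_right <= g.n_left else "left"

    host = g if enum_side == "right" else g.transpose()
    swap = enum_side == "left"

    collected: list[Biclique] | None = None if emit is not None else []
    count = 0

    def consume(l_mask: int, r_idx: tuple[int, ...]) -> None:
        nonlocal count
        left = host.left_mask_to_labels(l_mask)
        right = tuple(host.right_labels[j] for j in sorted(r_idx))
        b = Biclique(right, left) if swap else Biclique(left, right)
        count += 1
        if emit is not None:
            emit(b)
        else:
            collected.append(b)

    nodes, pruned, max_depth = _run(
        host._adj_right, host.n_left, range(host.n_right), algorithm, consume
    )
    return EnumerationResult(
        bicliques=collected,
        count=count,
        nodes=nodes,
        leaves_pruned=pruned,
        max_depth=max_depth,
        algorithm=algorithm,
        side=enum_side,
    )


def is_maximal(g: BipartiteGraph, b: Biclique) -> bool:
    """True iff no vertex outside either side extends ``b``.

    Precondition: ``b`` must be complete in ``g`` (every cross pair an
    edge); violating it raises :class:`ContractError`.
    """
    if not b.is_complete_in(g):
        raise ContractError("biclique is not complete in the host graph")
    lmask = g.left_subset_mask(b.left)
    rmask = g.right_subset_mask(b.right)
    for j in range(g.n_right):
        if not (rmask >> j) & 1 and g._adj_right[j] & lmask == lmask:
            return False
    for i in range(g.n_left):
        if not (lmask >> i) & 1 and g._adj_left[i] & rmask == rmask:
            return False
    return True


def _canonical_key(b: Biclique) -> tuple:
    return (tuple(sorted(map(str, b.left))), tuple(sorted(map(str, b.right))))


def _pick(bicliques: Iterable[Biclique], objective) -> Biclique:
    best = sorted(bicliques, key=_canonical_key)
    if not best:
        raise InputError("no bicliques to select from")
    return max(best, key=objective)  # max is stable: first canonical wins ties


def edge_maximum(result: EnumerationResult | Iterable[Biclique]) -> Biclique:
    """The biclique with the most edges (|left| * |right|); ties broken
    by canonical order."""
    return _pick(result, lambda b: b.n_edges)


def vertex_maximum(result: EnumerationResult | Iterable[Biclique]) -> Biclique:
    """The biclique with the most vertices (|left| + |right|); ties broken
    by canonical order."""
    return _pick(result, lambda b: b.n_vertices)
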