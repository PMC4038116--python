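"""Deliberately naive brute-force oracles, used only by the test suite.

These trade exponential time for obviousness: maximal bicliques by subset
enumeration over one partition with a Galois closure step, and maximal
cliques by pivotless recursion.  Hard caps refuse oversized inputs rather
than truncating — a truncated oracle would silently weaken the tests that
rely on it.
"""

from __future__ import annotations

from itertools import combinations

from .errors import InputError
from .graph_core import Biclique, BipartiteGraph, GeneralGraph, Label


def brute_force_bicliques(g: BipartiteGraph, cap: int = 20) -> set[Biclique]:
    """All maximal bicliques (both sides non-empty) by subset enumeration.

    Enumerates every non-empty subset R of the smaller partition, takes
    the common neighborhood L, and closes R to R* = {v : N(v) ⊇ L}; the
    pair (L, R*) is a closed (hence maximal) biclique, and every maximal
    biclique arises this way.  Refuses when the enumerated side exceeds
    ``cap`` (the 2^n blow-up guard).
    """
    host = g if g.n_right <= g.n_left else g.transpose()
    swap = host is not g
    n = host.n_right
    if n > cap:
        raise InputError(f"enumerated side has {n} vertices, above cap {cap}")
    adj = host._adj_right
    out: set[Biclique] = set()
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            L = (1 << host.n_left) - 1
            for j in subset:
                L &= adj[j]
            if not L:
                continue
            closure = tuple(j for j in range(n) if adj[j] & L == L)
            left = host.left_mask_to_labels(L)
            right = tuple(host.right_labels[j] for j in closure)
            out.add(Biclique(right, left) if swap else Biclique(left, right))
    return out


def brute_force_cliques(g: GeneralGraph, cap: int = 24) -> set[frozenset[Label]]:
    """All maximal cliques by pivotless recursive expansion."""
    if g.n_vertices > cap:
        raise InputError(f"{g.n_vertices} vertices, above cap {cap}")
    neigh = {a: g.neighbors(a) for a in g.labels}
    order = {a: i for i, a in enumerate(g.labels)}
    out: set[frozenset[Label]] = set()

    def grow(clique: set[Label], candidates: set[Label], excluded: set[Label]):
        if not candidates and not excluded:
            out.add(frozenset(clique))
            return
        for v in sorted(candidates, key=order.__getitem__):
            grow(clique | {v}, candidates & neigh[v], excluded & neigh[v])
            candidates = candidates - {v}
            excluded = excluded | {v}

    grow(set(), set(g.labels), set())
    return out
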