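"""Twin-vertex data reduction and exact post-processing expansion.

Vertices with identical neighborhoods (*twins*) always appear together in
every maximal biclique, so they can be merged into a single representative
before enumeration and re-expanded afterwards without changing the result.
Merging one partition can create new twins in the other, so reduction
alternates partitions until a fixpoint.

Degree-0 vertices all share the empty neighborhood; they are collected
into one block per partition, dropped from the reduced graph (with a
logged warning) and never re-appear, since bicliques require two non-empty
sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import InputError
from .graph_core import Biclique, BipartiteGraph, Label

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwinMapping:
    """Blocks of merged twins, one entry per surviving representative.

    Blocks within a partition are disjoint and cover every original vertex
    (including dropped degree-0 blocks, whose representatives do not occur
    in the reduced graph).  The original partition orders are retained so
    expanded bicliques can be re-canonicalized.
    """

    left_blocks: dict[Label, tuple[Label, ...]]
    right_blocks: dict[Label, tuple[Label, ...]]
    left_order: tuple[Label, ...]
    right_order: tuple[Label, ...]


def _merge_pass(
    labels: tuple[Label, ...], masks: list[int], blocks: dict[Label, tuple[Label, ...]]
) -> tuple[tuple[Label, ...], bool]:
    """Group vertices of one partition by neighborhood; keep first-in-order
    representatives; fold member blocks into the representative's block."""
    groups: dict[int, list[int]] = {}
    for idx, mask in enumerate(masks):
        groups.setdefault(mask, []).append(idx)
    changed = any(len(ix) > 1 for ix in groups.values())
    if not changed:
        return labels, False
    keep: list[Label] = []
    for mask, ix in sorted(groups.items(), key=lambda kv: kv[1][0]):
        rep = labels[ix[0]]
        merged: list[Label] = []
        for i in ix:
            merged.extend(blocks.pop(labels[i]))
        blocks[rep] = tuple(merged)
        keep.append(rep)
    return tuple(keep), True


def merge_twins(g: BipartiteGraph) -> tuple[BipartiteGraph, TwinMapping]:
    """Merge identical-neighborhood vertices to a fixpoint.

    Returns the reduced graph and the :class:`TwinMapping` needed by
    :func:`expand_bicliques` to restore results on the original graph.
    """
    left_blocks = {u: (u,) for u in g.left_labels}
    right_blocks = {v: (v,) for v in g.right_labels}
    cur = g
    n_iso = sum(m == 0 for m in cur._adj_left) + sum(m == 0 for m in cur._adj_right)
    if n_iso:
        logger.warning("dropping %d isolated (degree-0) vertex/vertices", n_iso)
    while True:
        right_labels, ch_r = _merge_pass(
            cur.right_labels, cur._adj_right, right_blocks
        )
        if ch_r:
            cur = _rebuild(cur, cur.left_labels, right_labels)
        left_labels, ch_l = _merge_pass(cur.left_labels, cur._adj_left, left_blocks)
        if ch_l:
            cur = _rebuild(cur, left_labels, cur.right_labels)
        if not (ch_r or ch_l):
            break
    # drop isolated representatives (neighborhood ∅ blocks)
    keep_l = tuple(u for u in cur.left_labels if cur._adj_left[cur.left_index(u)])
    keep_r = tuple(v for v in cur.right_labels if cur._adj_right[cur.right_index(v)])
    if len(keep_l) != cur.n_left or len(keep_r) != cur.n_right:
        cur = _rebuild(cur, keep_l, keep_r)
    mapping = TwinMapping(
        left_blocks=left_blocks,
        right_blocks=right_blocks,
        left_order=g.left_labels,
        right_order=g.right_labels,
    )
    return cur, mapping


def _rebuild(
    g: BipartiteGraph, left: tuple[Label, ...], right: tuple[Label, ...]
) -> BipartiteGraph:
    keep_l, keep_r = set(left), set(right)
    edges = [(u, v) for u, v in g.edges() if u in keep_l and v in keep_r]
    return BipartiteGraph(left, right, edges)


def expand_bicliques(
    bicliques: list[Biclique] | tuple[Biclique, ...], mapping: TwinMapping
) -> list[Biclique]:
    """Replace every representative by its full twin block.

    The biclique count is unchanged; members are re-canonicalized to the
    original graph's partition order.
    """
    l_pos = {u: i for i, u in enumerate(mapping.left_order)}
    r_pos = {v: j for j, v in enumerate(mapping.right_order)}
    out: list[Biclique] = []
    for b in bicliques:
        left: list[Label] = []
        right: list[Label] = []
        for u in b.left:
            try:
                left.extend(mapping.left_blocks[u])
            except KeyError:
                raise InputError(f"unknown left representative {u!r}") from None
        for v in b.right:
            try:
                right.extend(mapping.right_blocks[v])
            except KeyError:
                raise InputError(f"unknown right representative {v!r}") from None
        out.append(
            Biclique(
                tuple(sorted(left, key=l_pos.__getitem__)),
                tuple(sorted(right, key=r_pos.__getitem__)),
            )
        )
    return out
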