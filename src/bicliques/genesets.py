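"""Gene-set association graphs and the hierarchical biclique DAG.

In the gene-set setting the bipartite graph associates genes (left, the
``G`` side) with gene sets or phenotypes (right, the ``P`` side), built by
thresholding a real-valued score matrix such as correlation p-values.  A
maximal biclique then pairs a set of functions with exactly the genes they
share, and for maximal bicliques the two containment orders are dual:
P(b1) ⊂ P(b2) if and only if G(b1) ⊃ G(b2).

:func:`build_dag` orders maximal bicliques by strict containment of their
gene-set sides and keeps only the transitive reduction, producing a
hierarchy of functions: roots carry the fewest gene sets per node, and
following arcs downward narrows the gene-set side while enlarging the
shared gene side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np

from .errors import InputError
from .graph_core import Biclique, BipartiteGraph
from .io import ScoreMatrix, biclique_sort_key

DIRECTIONS = ("at_most", "at_least")


def threshold_to_graph(
    matrix: ScoreMatrix, direction: str, threshold: float
) -> BipartiteGraph:
    """Binarize a score matrix into a bipartite association graph.

    An edge (row, column) is present iff the cell value is non-missing and
    value ≤ threshold (``at_most``, e.g. p-values) or value ≥ threshold
    (``at_least``, e.g. correlations).  Both comparisons are inclusive.
    """
    if direction not in DIRECTIONS:
        raise InputError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if not math.isfinite(threshold):
        raise InputError("threshold must be finite")
    values = matrix.values
    keep = values <= threshold if direction == "at_most" else values >= threshold
    keep &= ~np.isnan(values)
    return BipartiteGraph.from_biadjacency(
        matrix.row_labels, matrix.col_labels, keep
    )


def check_duality(bicliques: Iterable[Biclique]) -> bool:
    """Verify the containment duality on every pair of maximal bicliques:
    strict containment of gene-set (right) sides must coincide with the
    reverse strict containment of gene (left) sides.  A failure indicates
    the input was not a set of maximal bicliques of one graph."""
    items = [(b.left_set, b.right_set) for b in bicliques]
    for i, (g1, p1) in enumerate(items):
        for g2, p2 in items[i + 1 :]:
            if (p1 < p2) != (g1 > g2) or (p2 < p1) != (g2 > g1):
                return False
    return True


@dataclass(frozen=True)
class BicliqueDAG:
    """Maximal bicliques ordered by gene-set containment, transitively
    reduced: an arc runs parent → child iff P(parent) ⊋ P(child) with no
    intermediate node between them."""

    nodes: tuple[Biclique, ...]
    arcs: tuple[tuple[Biclique, Biclique], ...]

    @property
    def roots(self) -> tuple[Biclique, ...]:
        children = {c for _, c in self.arcs}
        return tuple(b for b in self.nodes if b not in children)

    @property
    def leaves(self) -> tuple[Biclique, ...]:
        parents = {p for p, _ in self.arcs}
        return tuple(b for b in self.nodes if b not in parents)

    def parents(self, b: Biclique) -> tuple[Biclique, ...]:
        return tuple(p for p, c in self.arcs if c == b)

    def children(self, b: Biclique) -> tuple[Biclique, ...]:
        return tuple(c for p, c in self.arcs if p == b)


def build_dag(bicliques: Sequence[Biclique]) -> BicliqueDAG:
    """Order maximal bicliques into a hierarchical similarity DAG.

    Ancestry is strict containment of the gene-set (right) sides; arcs are
    the transitive reduction of that order.  Distinct maximal bicliques of
    one graph can never share a gene-set side (equal P forces equal G by
    maximality), so duplicates are rejected as input errors.
    """
    nodes = sorted(bicliques, key=biclique_sort_key)
    if len(set(nodes)) != len(nodes):
        raise InputError("duplicate bicliques in DAG input")
    psides = [b.right_set for b in nodes]
    k = len(nodes)
    ancestor = [[psides[j] < psides[i] for j in range(k)] for i in range(k)]
    arcs: list[tuple[Biclique, Biclique]] = []
    for i in range(k):
        for j in range(k):
            if not ancestor[i][j]:
                continue
            if any(ancestor[i][t] and ancestor[t][j] for t in range(k)):
                continue  # implied through an intermediate: not a parent arc
            arcs.append((nodes[i], nodes[j]))
    return BicliqueDAG(nodes=tuple(nodes), arcs=tuple(arcs))


def export_dag(dag: BicliqueDAG, sink: IO[str]) -> None:
    """Write the DAG in DOT format, deterministically ordered.

    Node labels read "<|G(b)|> genes / <sorted P(b) members>".
    """
    index = {b: i for i, b in enumerate(dag.nodes)}
    sink.write("digraph bicliques {\n")
    for i, b in enumerate(dag.nodes):
        label = f"{b.n_left} genes / " + ",".join(sorted(map(str, b.right)))
        sink.write(f'  n{i} [label="{label}"];\n')
    for p, c in sorted(dag.arcs, key=lambda pc: (index[pc[0]], index[pc[1]])):
        sink.write(f"  n{index[p]} -> n{index[c]};\n")
    sink.write("}\n")
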