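"""Readers and writers: edge lists, score matrices, bicliques, transactions.

Edge lists come in two dialects.  *dimacs* is a simplified DIMACS style:
comment lines start with ``c``, an optional single problem line
``p <m> <n> <e>`` declares the partition and edge counts, and each edge
line reads ``e <left_label> <right_label>``.  *bare* is a permissive
fallback: one whitespace-separated label pair per line, ``#`` comments.
Column 1 is always the left partition.  Labels are UTF-8 and may not
contain whitespace.

All writers are deterministic: the same in-memory object always produces
byte-identical text.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InputError, ParseError
from .graph_core import Biclique, BipartiteGraph, GeneralGraph, _mask_indices

Source = Union[str, Path, IO[str], Iterable[str]]

DIALECTS = ("dimacs", "bare")
_COMMENT = {"dimacs": "c", "bare": "#"}


@dataclass(frozen=True)
class EdgeListDialect:
    """Line grammar selector for edge-list text."""

    style: str = "dimacs"
    comment_prefix: str | None = None

    def __post_init__(self):
        if self.style not in DIALECTS:
            raise InputError(f"unknown edge-list style {self.style!r}")

    @property
    def comment(self) -> str:
        return self.comment_prefix or _COMMENT[self.style]


@dataclass
class ScoreMatrix:
    """A labeled real-valued matrix; NaN marks missing cells."""

    table: pd.DataFrame

    @property
    def row_labels(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @property
    def col_labels(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.table.shape


def _lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def read_edge_list(
    source: Source, dialect: EdgeListDialect | str = "dimacs"
) -> BipartiteGraph:
    """Parse an edge list into a bipartite graph.

    Vertices appear in first-encounter order.  In the dimacs dialect a
    problem line, when present, must agree with the observed distinct
    label and (deduplicated) edge counts.
    """
    if isinstance(dialect, str):
        dialect = EdgeListDialect(dialect)
    dimacs = dialect.style == "dimacs"
    left: dict[str, None] = {}
    right: dict[str, None] = {}
    edges: list[tuple[str, str]] = []
    declared: tuple[int, int, int] | None = None
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith(dialect.comment):
            continue
        tokens = line.split()
        if dimacs and tokens[0] == "p":
            if declared is not None:
                raise ParseError("duplicate problem line", lineno)
            if edges:
                raise ParseError("problem line after edge lines", lineno)
            if len(tokens) != 4:
                raise ParseError(f"problem line needs 3 counts: {line!r}", lineno)
            try:
                declared = tuple(int(t) for t in tokens[1:])  # type: ignore[assignment]
            except ValueError:
                raise ParseError(f"non-integer count in {line!r}", lineno) from None
            continue
        if dimacs:
            if tokens[0] != "e" or len(tokens) != 3:
                raise ParseError(f"expected 'e <u> <v>', got {line!r}", lineno)
            u, v = tokens[1], tokens[2]
        else:
            if len(tokens) != 2:
                raise ParseError(f"expected '<u> <v>', got {line!r}", lineno)
            u, v = tokens
        left.setdefault(u)
        right.setdefault(v)
        edges.append((u, v))
    g = BipartiteGraph(tuple(left), tuple(right), edges)
    if declared is not None:
        m, n, e = declared
        if (m, n, e) != (g.n_left, g.n_right, g.n_edges):
            raise ParseError(
                f"problem line declares m={m} n={n} e={e} but observed "
                f"m={g.n_left} n={g.n_right} e={g.n_edges}"
            )
    return g


def write_edge_list(
    sink: IO[str], g: BipartiteGraph, dialect: EdgeListDialect | str = "dimacs"
) -> int:
    """Write a graph as an edge list; returns the number of edge lines.

    Isolated vertices are unrepresentable in an edge list, so the dimacs
    problem line declares the counts of vertices that occur in edges —
    exactly what a reader of the output will observe.
    """
    if isinstance(dialect, str):
        dialect = EdgeListDialect(dialect)
    count = 0
    if dialect.style == "dimacs":
        m_obs = sum(1 for mask in g._adj_left if mask)
        n_obs = sum(1 for mask in g._adj_right if mask)
        sink.write(f"p {m_obs} {n_obs} {g.n_edges}\n")
        for u, v in g.edges():
            sink.write(f"e {u} {v}\n")
            count += 1
    else:
        for u, v in g.edges():
            sink.write(f"{u} {v}\n")
            count += 1
    return count


def write_general_edge_list(sink: IO[str], g: GeneralGraph) -> int:
    """Write an undirected graph as bare label pairs, deterministically."""
    order = {lab: i for i, lab in enumerate(g.labels)}
    pairs = sorted(
        (sorted(e, key=order.__getitem__) for e in g.edge_set),
        key=lambda ab: (order[ab[0]], order[ab[1]]),
    )
    for a, b in pairs:
        sink.write(f"{a} {b}\n")
    return len(pairs)


def read_score_matrix(source: Source, delimiter: str = "\t") -> ScoreMatrix:
    """Parse a delimited table: header row of column labels, first column
    of row labels, numeric or empty cells (empty = missing, never zero)."""
    rows = list(csv.reader(_lines(source), delimiter=delimiter))
    rows = [r for r in rows if r]
    if not rows:
        raise ParseError("empty score matrix")
    header = rows[0][1:]
    if len(set(header)) != len(header):
        raise ParseError("duplicate column labels")
    width = len(rows[0])
    labels: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"ragged row: {len(row)} cells, expected {width}", lineno
            )
        labels.append(row[0])
        parsed: list[float] = []
        for col, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "":
                parsed.append(float("nan"))
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r} at row {row[0]!r}, "
                    f"column {header[col]!r}",
                    lineno,
                ) from None
        data.append(parsed)
    if len(set(labels)) != len(labels):
        raise ParseError("duplicate row labels")
    table = pd.DataFrame(data, index=labels, columns=header, dtype=float)
    return ScoreMatrix(table)


def biclique_sort_key(b: Biclique) -> tuple:
    return (tuple(sorted(map(str, b.left))), tuple(sorted(map(str, b.right))))


def write_bicliques(
    sink: IO[str], bicliques: Sequence[Biclique], format: str = "tsv"
) -> int:
    """Write bicliques, one per line, in a canonical sorted order.

    tsv: space-joined sorted left members, a tab, space-joined sorted
    right members; lines sorted lexicographically.  json-lines: one object
    per line with left/right member lists and size fields, same ordering.
    Byte-identical across runs on equal input sets.
    """
    if format not in ("tsv", "json-lines"):
        raise InputError(f"unknown biclique format {format!r}")
    ordered = sorted(bicliques, key=biclique_sort_key)
    for b in ordered:
        left = sorted(map(str, b.left))
        right = sorted(map(str, b.right))
        if format == "tsv":
            sink.write(" ".join(left) + "\t" + " ".join(right) + "\n")
        else:
            sink.write(
                json.dumps(
                    {
                        "left": left,
                        "right": right,
                        "n_left": b.n_left,
                        "n_right": b.n_right,
                        "n_edges": b.n_edges,
                    },
                    separators=(", ", ": "),
                )
                + "\n"
            )
    return len(ordered)


def read_bicliques(source: Source) -> list[Biclique]:
    """Parse the tsv biclique format back into :class:`Biclique` objects."""
    out: list[Biclique] = []
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError("expected '<left members>\\t<right members>'", lineno)
        left, right = parts[0].split(), parts[1].split()
        if not left or not right:
            raise ParseError("biclique sides must be non-empty", lineno)
        out.append(Biclique(tuple(left), tuple(right)))
    return out


def write_transactions(sink: IO[str], g: BipartiteGraph) -> int:
    """Itemset-mining interchange: one line per right vertex (transaction)
    listing its left neighbors (items) space-separated, in partition order.
    Isolated right vertices emit empty lines."""
    for v in g.right_labels:
        mask = g._adj_right[g.right_index(v)]
        items = [str(g.left_labels[i]) for i in _mask_indices(mask)]
        sink.write(" ".join(items) + "\n")
    return g.n_right
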