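"""Readers and writers for graphs and derived matrices.

Supported graph formats: 2-column edge-list TSV, square adjacency CSV/TSV
(optional header row of labels), and GraphML (vertex ``category``
attributes survive a round trip).  Laplacians export as Matrix Market.
Vertex labels are preserved verbatim in every direction.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from .graph_core import Graph, GraphError, laplacian

__all__ = [
    "read_graph",
    "write_graph",
    "read_edgelist",
    "write_edgelist",
    "read_adjacency",
    "read_graphml",
    "write_graphml",
    "write_laplacian_mm",
]

_FORMATS = ("edgelist", "adjacency", "graphml")


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix in (".csv",):
        return "adjacency"
    return "edgelist"


def read_graph(path, fmt: str | None = None, symmetrize: bool = False) -> Graph:
    """Read a graph, inferring the format from the extension when ``fmt``
    is not given (.graphml -> GraphML, .csv -> adjacency, else edge list)."""
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    if fmt == "graphml":
        return read_graphml(path)
    if fmt == "adjacency":
        return read_adjacency(path, symmetrize=symmetrize)
    if fmt == "edgelist":
        return read_edgelist(path)
    raise GraphError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_graph(g: Graph, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    if fmt == "graphml":
        write_graphml(g, path)
    elif fmt == "edgelist":
        write_edgelist(g, path)
    else:
        raise GraphError(f"unsupported output format {fmt!r}")


def read_edgelist(path) -> Graph:
    """Two-column TSV of edge endpoints; ``#``-prefixed lines are
    comments.  An optional comment header ``# vertices: a b c`` pins the
    vertex order and records isolated vertices."""
    path = Path(path)
    edges = []
    declared: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("vertices:"):
                    declared = body[len("vertices:") :].split()
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GraphError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            edges.append((parts[0], parts[1]))
    if declared is None:
        seen: dict[str, None] = {}
        for u, v in edges:
            seen.setdefault(u)
            seen.setdefault(v)
        declared = list(seen)
    return Graph.from_edges(declared, edges)


def write_edgelist(g: Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# vertices: " + " ".join(g.vertices) + "\n")
        for u, v in g.edge_list():
            fh.write(f"{u}\t{v}\n")


def read_adjacency(
    path,
    labels: Sequence[str] | None = None,
    symmetrize: bool = False,
) -> Graph:
    """Square adjacency CSV/TSV.  A non-numeric first row is taken as the
    label header.  ``symmetrize`` accepts an asymmetric (directed count)
    matrix and folds it as A + A^T before binarizing."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim) if r and any(x.strip() for x in r)]
    if not rows:
        raise GraphError(f"{path}: empty file")
    header: list[str] | None = None
    try:
        float(rows[0][0])
    except ValueError:
        header = [x.strip() for x in rows[0]]
        rows = rows[1:]
    try:
        a = np.array([[float(x) for x in r] for r in rows])
    except ValueError as exc:
        raise GraphError(f"{path}: non-numeric entry: {exc}") from None
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise GraphError(f"{path}: adjacency must be square, got {a.shape}")
    if symmetrize:
        a = a + a.T
    labels = list(labels) if labels is not None else header
    return Graph.from_adjacency((a > 0).astype(float), labels)


def read_graphml(path) -> Graph:
    return Graph.from_networkx(nx.read_graphml(Path(path)))


def write_graphml(g: Graph, path) -> None:
    nx.write_graphml(g.to_networkx(), Path(path))


def write_laplacian_mm(g: Graph, path) -> None:
    """Laplacian as a Matrix Market coordinate file (full precision)."""
    mmwrite(str(path), csr_matrix(laplacian(g)), precision=17)
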