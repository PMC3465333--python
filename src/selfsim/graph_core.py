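"""Graph data model, connectome assembly, and Laplacian construction.

The central object is :class:`Graph`: a simple undirected graph with an
ordered list of string vertex labels.  The order is significant — it fixes
the row/column indexing of every matrix derived from the graph (adjacency,
Laplacian, degree-normalized Laplacian) and makes all downstream spectral
output deterministic.

A connectome is assembled from two raw adjacency matrices: a directed
chemical-synapse matrix ``C`` (entry counts, possibly asymmetric) and a
symmetric gap-junction matrix ``G``.  Directionality and multiplicity are
deliberately discarded: the combined matrix ``C + C^T + G`` is binarized,
self-loops dropped, leaving only the skeleton of who-touches-whom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "GraphError",
    "assemble_connectome",
    "giant_component",
    "degrees",
    "laplacian",
    "NormalizedLaplacian",
    "normalized_laplacian",
]


class GraphError(ValueError):
    """Invalid graph construction or operation."""


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph with ordered, labelled vertices.

    Parameters
    ----------
    vertices
        Ordered vertex labels; order defines matrix indexing.
    edges
        Unordered label pairs.  Self-loops and duplicates are rejected.
    categories
        Optional label -> category map (e.g. neuron type), passed through
        to coordinate exports for colouring.
    """

    vertices: tuple[str, ...]
    edges: frozenset[frozenset]
    categories: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        labels = set(self.vertices)
        if len(labels) != len(self.vertices):
            raise GraphError("duplicate vertex labels")
        for e in self.edges:
            if len(e) != 2:
                raise GraphError(f"self-loop or malformed edge: {set(e)}")
            if not e <= labels:
                raise GraphError(f"edge endpoints not in vertex set: {set(e)}")

    @classmethod
    def from_edges(
        cls,
        vertices: Iterable[str],
        edges: Iterable[tuple[str, str]],
        categories: dict | None = None,
    ) -> "Graph":
        es = frozenset(frozenset((str(u), str(v))) for u, v in edges)
        return cls(tuple(str(v) for v in vertices), es, dict(categories or {}))

    @classmethod
    def from_adjacency(
        cls, a: np.ndarray, labels: Sequence[str] | None = None
    ) -> "Graph":
        """Build from a symmetric nonnegative matrix; entries binarized,
        diagonal ignored."""
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise GraphError(f"adjacency must be square, got shape {a.shape}")
        if (a < 0).any():
            raise GraphError("adjacency entries must be nonnegative")
        if not np.array_equal(a, a.T):
            raise GraphError("adjacency must be symmetric (symmetrize first)")
        n = a.shape[0]
        if labels is None:
            labels = [str(i + 1) for i in range(n)]  # 1-based external labels
        elif len(labels) != n:
            raise GraphError("label count does not match matrix dimension")
        labels = [str(x) for x in labels]
        ii, jj = np.nonzero(np.triu(a, k=1))
        return cls.from_edges(labels, [(labels[i], labels[j]) for i, j in zip(ii, jj)])

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        cats = {str(v): d["category"] for v, d in g.nodes(data=True) if "category" in d}
        return cls.from_edges(
            [str(v) for v in g.nodes()],
            [(str(u), str(v)) for u, v in g.edges() if u != v],
            cats,
        )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def m(self) -> int:
        return len(self.edges)

    def index(self) -> dict:
        return {v: i for i, v in enumerate(self.vertices)}

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges as label pairs, sorted by vertex order (deterministic)."""
        idx = self.index()
        pairs = [tuple(sorted(e, key=idx.__getitem__)) for e in self.edges]
        return sorted(pairs, key=lambda p: (idx[p[0]], idx[p[1]]))

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges

    def neighbors(self, v: str) -> list[str]:
        idx = self.index()
        out = [next(iter(e - {v})) for e in self.edges if v in e]
        return sorted(out, key=idx.__getitem__)

    def adjacency(self) -> np.ndarray:
        idx = self.index()
        a = np.zeros((self.n, self.n))
        for e in self.edges:
            u, v = tuple(e)
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edge_list())
        for v, c in self.categories.items():
            if v in g:
                g.nodes[v]["category"] = c
        return g

    def subgraph(self, keep: Iterable[str]) -> "Graph":
        keep = set(keep)
        verts = tuple(v for v in self.vertices if v in keep)
        edges = frozenset(e for e in self.edges if e <= keep)
        cats = {v: c for v, c in self.categories.items() if v in keep}
        return Graph(verts, edges, cats)


# ----------------------------------------------------------------------
def assemble_connectome(
    chem: np.ndarray,
    gap: np.ndarray,
    labels: Sequence[str] | None = None,
    categories: dict | None = None,
) -> Graph:
    """Combine chemical-synapse and gap-junction adjacency matrices.

    The chemical matrix may be directed; it is symmetrized by adding its
    transpose.  The sum ``chem + chem.T + gap`` is then binarized and the
    diagonal discarded, so the result is simple and undirected regardless
    of connection multiplicities.
    """
    chem = np.asarray(chem, dtype=float)
    gap = np.asarray(gap, dtype=float)
    if chem.ndim != 2 or chem.shape[0] != chem.shape[1]:
        raise GraphError(f"chemical matrix must be square, got {chem.shape}")
    if gap.shape != chem.shape:
        raise GraphError(
            f"dimension mismatch: chemical {chem.shape} vs gap-junction {gap.shape}"
        )
    if (chem < 0).any() or (gap < 0).any():
        raise GraphError("connection counts must be nonnegative")
    combined = chem + chem.T + gap
    np.fill_diagonal(combined, 0.0)
    a = (combined > 0).astype(float)
    g = Graph.from_adjacency(a, labels)
    if categories:
        return Graph(g.vertices, g.edges, dict(categories))
    return g


def giant_component(g: Graph) -> Graph:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken by the component containing the
    smallest-indexed vertex, so the result is deterministic.
    """
    if g.n == 0:
        raise GraphError("empty graph has no components")
    idx = g.index()
    comps = list(nx.connected_components(g.to_networkx()))
    comps.sort(key=lambda c: (-len(c), min(idx[v] for v in c)))
    return g.subgraph(comps[0])


def degrees(g: Graph) -> np.ndarray:
    """Degree of each vertex, in vertex order."""
    idx = g.index()
    d = np.zeros(g.n)
    for e in g.edges:
        for v in e:
            d[idx[v]] += 1
    return d


def laplacian(g: Graph) -> np.ndarray:
    """Combinatorial Laplacian L = D - A (symmetric PSD, zero row sums)."""
    a = g.adjacency()
    return np.diag(a.sum(axis=1)) - a


@dataclass(frozen=True)
class NormalizedLaplacian:
    """Degree-normalized Laplacian D^{-1/2} L D^{-1/2}.

    Shares its spectrum (contained in [0, 2]) with the generalized problem
    L f = lambda D f; generalized eigenvectors are recovered from symmetric
    ones via :meth:`back_transform`, under which the bottom eigenfunction
    is constant.
    """

    matrix: np.ndarray
    d_inv_sqrt: np.ndarray  # diagonal of D^{-1/2}

    def back_transform(self, vectors: np.ndarray) -> np.ndarray:
        """Map eigenvectors of the symmetric form to vertex functions
        solving L f = lambda D f (columns are vectors)."""
        return self.d_inv_sqrt[:, None] * np.atleast_2d(vectors.T).T


def normalized_laplacian(g: Graph) -> NormalizedLaplacian:
    d = degrees(g)
    if (d == 0).any():
        zero = [g.vertices[i] for i in np.nonzero(d == 0)[0]]
        raise GraphError(
            f"zero-degree vertices {zero[:5]}: extract the giant component first"
        )
    dis = 1.0 / np.sqrt(d)
    lap = laplacian(g)
    s = dis[:, None] * lap * dis[None, :]
    return NormalizedLaplacian((s + s.T) / 2.0, dis)
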