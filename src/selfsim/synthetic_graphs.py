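"""Seeded generators for every comparison graph in the analysis.

Covers Erdos-Renyi G(n, p) random graphs, random branching trees with a
bounded number of children per branch point, level-m graph approximations
of the Sierpinski gasket and of the hexacarpet, probabilistic edge
rewiring, and density-matched random graphs.

All generators are deterministic for a fixed seed, and the fractal
generators are fully deterministic: vertex labels are assigned by a
canonical geometric ordering so repeated runs are bit-identical.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np

from .graph_core import Graph, GraphError

__all__ = [
    "random_gnp",
    "random_tree",
    "sierpinski_gasket",
    "hexacarpet",
    "rewire",
    "matched_random",
    "matched_p",
]


def random_gnp(n: int, p: float, seed: int | None = None) -> Graph:
    """Erdos-Renyi random graph: each of the n(n-1)/2 vertex pairs is an
    edge independently with probability p."""
    if n < 1:
        raise GraphError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise GraphError(f"connection probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    labels = [str(i + 1) for i in range(n)]
    pairs = list(combinations(range(n), 2))
    mask = rng.random(len(pairs)) < p
    edges = [(labels[i], labels[j]) for (i, j), hit in zip(pairs, mask) if hit]
    return Graph.from_edges(labels, edges)


def random_tree(n: int, max_children: int, seed: int | None = None) -> Graph:
    """Random branching tree on n vertices.

    Vertices are processed in breadth order.  Each branch point draws its
    number of children uniformly from {1, ..., max_children}, capped by the
    remaining vertex budget, and attaches the next not-yet-connected
    vertices.  The result is always connected and acyclic with n - 1 edges;
    max_children = 1 forces a path.
    """
    if n < 1:
        raise GraphError("n must be >= 1")
    if max_children < 1:
        raise GraphError("max_children must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [str(i + 1) for i in range(n)]
    edges = []
    next_child = 1  # 0-based index of first unconnected vertex
    v = 0
    while next_child < n:
        k = int(rng.integers(1, max_children + 1))
        k = min(k, n - next_child)  # never exceed the fixed vertex count
        for c in range(next_child, next_child + k):
            edges.append((labels[v], labels[c]))
        next_child += k
        v += 1
    return Graph.from_edges(labels, edges)


def _gasket_triangles(level: int):
    """Corner triples of the 3**level smallest triangles, on an integer
    lattice scaled so that all midpoints stay integral."""
    s = 2**level
    tris = [((0, 0), (s, 0), (0, s))]
    for _ in range(level):
        new = []
        for a, b, c in tris:
            mab = ((a[0] + b[0]) // 2, (a[1] + b[1]) // 2)
            mbc = ((b[0] + c[0]) // 2, (b[1] + c[1]) // 2)
            mca = ((c[0] + a[0]) // 2, (c[1] + a[1]) // 2)
            new += [(a, mab, mca), (mab, b, mbc), (mca, mbc, c)]
        tris = new
    return tris


def sierpinski_gasket(level: int) -> Graph:
    """Level-m graph approximation of the Sierpinski gasket.

    Level 0 is a triangle; level m glues three level-(m-1) copies at their
    outer corners.  Vertex count (3**(m+1) + 3) / 2, edge count 3**(m+1).
    Labels are 1..n in lexicographic order of the canonical lattice
    coordinates, so construction is bit-reproducible.
    """
    if level < 0:
        raise GraphError("level must be >= 0")
    tris = _gasket_triangles(level)
    points = sorted({p for t in tris for p in t})
    label = {p: str(i + 1) for i, p in enumerate(points)}
    edges = set()
    for t in tris:
        for u, v in combinations(t, 2):
            edges.add((label[u], label[v]))
    return Graph.from_edges([label[p] for p in points], edges)


def _subdivide(tri):
    """Barycentric subdivision of a triangle into six triangles."""
    a, b, c = tri
    mid = lambda p, q: tuple((pi + qi) / 2 for pi, qi in zip(p, q))
    g = tuple(sum(pi for pi in xs) / 3 for xs in zip(a, b, c))
    mab, mbc, mca = mid(a, b), mid(b, c), mid(c, a)
    return [
        (a, mab, g), (mab, b, g), (b, mbc, g),
        (mbc, c, g), (c, mca, g), (mca, a, g),
    ]


def hexacarpet(level: int) -> Graph:
    """Level-m hexacarpet graph approximation.

    Vertices are the 6**m faces of the m-fold repeated barycentric
    subdivision of a triangle; two faces are adjacent when they share an
    edge (a 1-dimensional boundary).  Level 1 is a 6-cycle.  Coordinates
    are exact rationals so face identification is robust.
    """
    if level < 1:
        raise GraphError("level must be >= 1 (level 0 has a single face)")
    one = Fraction(1)
    tris = [((one * 0, one * 0), (one, one * 0), (one * 0, one))]
    for _ in range(level):
        tris = [t for tri in tris for t in _subdivide(tri)]
    faces = [tuple(sorted(t)) for t in tris]
    order = sorted(range(len(faces)), key=faces.__getitem__)
    label = {faces[i]: str(r + 1) for r, i in enumerate(order)}
    edge_owner: dict = {}
    adj = set()
    for f in faces:
        for u, v in combinations(f, 2):
            key = (u, v)
            if key in edge_owner:
                adj.add((label[edge_owner[key]], label[f]))
            else:
                edge_owner[key] = f
    verts = [label[faces[i]] for i in order]
    return Graph.from_edges(verts, adj)


def rewire(g: Graph, p: float, seed: int | None = None) -> Graph:
    """Randomly rewire each edge with probability p.

    A selected edge {i, j} (i before j in vertex order) keeps its
    lower-indexed endpoint i; the other endpoint moves to a uniformly
    chosen vertex not already adjacent to i.  Edge count and simplicity
    are preserved; a rewire with no available target is skipped.
    """
    if not 0.0 <= p <= 1.0:
        raise GraphError(f"rewire probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    idx = g.index()
    adj = {v: set(g.neighbors(v)) for v in g.vertices}
    for u, v in g.edge_list():
        if rng.random() >= p:
            continue
        candidates = [w for w in g.vertices if w != u and w not in adj[u]]
        if not candidates:
            continue  # u adjacent to all others: skip this rewire
        w = candidates[int(rng.integers(len(candidates)))]
        adj[u].remove(v)
        adj[v].remove(u)
        adj[u].add(w)
        adj[w].add(u)
    edges = {tuple(sorted((u, w), key=idx.__getitem__)) for u in adj for w in adj[u]}
    return Graph.from_edges(g.vertices, edges, g.categories)


def matched_p(g: Graph) -> float:
    """Edge probability matching g's density: |E| / (n(n-1)/2)."""
    if g.n < 2:
        raise GraphError("need at least 2 vertices to define a density")
    return g.m / (g.n * (g.n - 1) / 2)


def matched_random(g: Graph, seed: int | None = None) -> tuple[Graph, float]:
    """G(n, p) with n and edge density matched to g; returns (graph, p)."""
    p = matched_p(g)
    return random_gnp(g.n, p, seed), p
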