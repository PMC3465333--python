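"""Clustering coefficients, shortest paths, and the matched-random
small-world comparison.

A network is small-world in the Watts-Strogatz sense when its average
clustering coefficient is much larger than that of a density-matched
random graph while its average path length stays comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graph_core import Graph, giant_component
from .synthetic_graphs import matched_random

__all__ = [
    "ClusteringStats",
    "clustering",
    "PathStats",
    "shortest_paths",
    "SmallWorldReport",
    "small_world_report",
]


@dataclass(frozen=True)
class ClusteringStats:
    """Per-vertex clustering coefficients and their average.

    c_v = e_v / (k_v (k_v - 1) / 2), the fraction of realized connections
    among the k_v neighbours of v; vertices of degree < 2 contribute 0 and
    are included in the average.
    """

    per_vertex: dict  # label -> c_v
    neighbor_edges: dict  # label -> e_v
    degree: dict  # label -> k_v
    average: float


def clustering(g: Graph) -> ClusteringStats:
    a = g.adjacency()
    k = a.sum(axis=1)
    # e_v = number of edges among neighbours of v = (A^3)_vv / 2
    ev = np.diag(a @ a @ a) / 2.0
    possible = k * (k - 1) / 2.0
    cv = np.divide(ev, possible, out=np.zeros_like(ev), where=possible > 0)
    labels = g.vertices
    return ClusteringStats(
        per_vertex={v: float(c) for v, c in zip(labels, cv)},
        neighbor_edges={v: int(round(e)) for v, e in zip(labels, ev)},
        degree={v: int(d) for v, d in zip(labels, k)},
        average=float(cv.mean()) if g.n else 0.0,
    )


@dataclass(frozen=True)
class PathStats:
    """All-pairs shortest hop distances.

    ``average`` is the arithmetic mean over unordered reachable pairs
    (single-source breadth-first search per vertex — Dijkstra with unit
    weights); ``fraction_reachable`` flags disconnection.
    """

    distances: np.ndarray  # inf for unreachable pairs
    average: float
    diameter: float
    fraction_reachable: float


def shortest_paths(g: Graph) -> PathStats:
    a = csr_matrix(g.adjacency())
    d = shortest_path(a, method="D", unweighted=True, directed=False)
    iu = np.triu_indices(g.n, k=1)
    vals = d[iu]
    finite = np.isfinite(vals)
    avg = float(vals[finite].mean()) if finite.any() else float("nan")
    diam = float(vals[finite].max()) if finite.any() else float("nan")
    frac = float(finite.mean()) if vals.size else 1.0
    return PathStats(d, avg, diam, frac)


@dataclass(frozen=True)
class SmallWorldReport:
    """Clustering / path-length comparison against matched random graphs."""

    n: int
    m: int
    clustering_avg: float
    path_length_avg: float
    matched_p: float
    seeds: tuple[int, ...]
    random_clustering_avg: float
    random_path_length_avg: float
    random_disconnected_fraction: float  # realizations needing a component cut
    per_seed: list = field(repr=False, default_factory=list)

    @property
    def clustering_ratio(self) -> float:
        r = self.random_clustering_avg
        return self.clustering_avg / r if r > 0 else float("inf")

    @property
    def path_length_ratio(self) -> float:
        r = self.random_path_length_avg
        return self.path_length_avg / r if r > 0 else float("inf")

    def is_small_world(self, clustering_factor: float = 2.0, path_factor: float = 2.0) -> bool:
        """Watts-Strogatz verdict: clustering well above random, path
        length within a modest factor of random."""
        return (
            self.clustering_ratio >= clustering_factor
            and self.path_length_ratio <= path_factor
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "edges": self.m,
            "clustering_avg": self.clustering_avg,
            "path_length_avg": self.path_length_avg,
            "matched_p": self.matched_p,
            "seeds": list(self.seeds),
            "random_clustering_avg": self.random_clustering_avg,
            "random_path_length_avg": self.random_path_length_avg,
            "random_disconnected_fraction": self.random_disconnected_fraction,
            "clustering_ratio": self.clustering_ratio,
            "path_length_ratio": self.path_length_ratio,
            "small_world": self.is_small_world(),
            "per_seed": self.per_seed,
        }


def small_world_report(g: Graph, seeds=range(25)) -> SmallWorldReport:
    """Compare g's clustering and path length with density-matched G(n, p)
    realizations, one per seed.

    Disconnected random realizations have their path length computed on
    the largest component (clustering is over all vertices either way);
    the fraction of such realizations is reported.
    """
    cs = clustering(g)
    ps = shortest_paths(g)
    per_seed = []
    disconnected = 0
    p_used = None
    for seed in seeds:
        rg, p_used = matched_random(g, seed)
        rc = clustering(rg).average
        rps = shortest_paths(rg)
        if rps.fraction_reachable < 1.0:
            disconnected += 1
            rl = shortest_paths(giant_component(rg)).average
        else:
            rl = rps.average
        per_seed.append({"seed": int(seed), "clustering": rc, "path_length": rl})
    seeds = tuple(int(s) for s in seeds)
    return SmallWorldReport(
        n=g.n,
        m=g.m,
        clustering_avg=cs.average,
        path_length_avg=ps.average,
        matched_p=float(p_used),
        seeds=seeds,
        random_clustering_avg=float(np.mean([r["clustering"] for r in per_seed])),
        random_path_length_avg=float(np.mean([r["path_length"] for r in per_seed])),
        random_disconnected_fraction=disconnected / max(len(seeds), 1),
        per_seed=per_seed,
    )
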