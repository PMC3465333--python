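"""Eigendecomposition, eigenvalue counting function, Weyl ratios, and
eigen-projection coordinates.

The eigenvalue counting function N(x) — the number of Laplacian
eigenvalues at most x — is the workhorse: fractal graph approximations
show flat "spectral gap" steps in N, while random graphs do not.  Dividing
out the fitted power-law growth x^alpha gives the Weyl ratio
W(x) = N(x) / x^alpha, whose log-periodic oscillation is a signature of
spectral self-similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import (
    Graph,
    GraphError,
    NormalizedLaplacian,
    degrees,
    giant_component,
    laplacian,
    normalized_laplacian,
)

__all__ = [
    "Spectrum",
    "spectrum",
    "counting_function",
    "counting_curve",
    "spectral_gaps",
    "AlphaFit",
    "fit_alpha",
    "weyl_ratio",
    "eigen_projection",
]

#: absolute tie tolerance for lambda <= x comparisons on floating-point
#: eigenvalues
EIG_TOL = 1e-9


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Scale each column so its largest-magnitude entry is positive
    (first such index on ties) — makes eigenfunction output deterministic
    up to the solver's basis choice inside degenerate eigenspaces."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


@dataclass(frozen=True)
class Spectrum:
    """Ascending eigenvalues with orthonormal eigenfunctions.

    ``source`` records whether the matrix was the combinatorial Laplacian
    or its degree-normalized form.
    """

    eigenvalues: np.ndarray
    eigenfunctions: np.ndarray  # column i is the i-th eigenfunction
    source: str = "laplacian"

    @property
    def n(self) -> int:
        return self.eigenvalues.size

    def multiplicities(self, tol: float = 1e-8) -> list[tuple[float, int]]:
        """Distinct eigenvalues with multiplicities (values within tol of
        each other are grouped)."""
        out: list[list] = []
        for lam in self.eigenvalues:
            if out and lam - out[-1][0] <= tol:
                out[-1][1] += 1
            else:
                out.append([float(lam), 1])
        return [(v, k) for v, k in out]


def spectrum(matrix: np.ndarray | NormalizedLaplacian, source: str | None = None) -> Spectrum:
    """Full dense symmetric eigendecomposition, ascending order,
    deterministic sign convention."""
    if isinstance(matrix, NormalizedLaplacian):
        m = matrix.matrix
        source = source or "normalized"
    else:
        m = np.asarray(matrix, dtype=float)
        source = source or "laplacian"
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise GraphError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise GraphError("matrix is not symmetric")
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    return Spectrum(vals, _fix_signs(vecs), source)


def counting_function(s: Spectrum, x: float | np.ndarray) -> int | np.ndarray:
    """N(x) = #{i : lambda_i <= x + tol}; right-continuous step function."""
    counts = np.searchsorted(s.eigenvalues, np.asarray(x) + EIG_TOL, side="right")
    return int(counts) if np.isscalar(x) else counts


def counting_curve(s: Spectrum) -> np.ndarray:
    """The counting function as its jump points: rows (lambda, N(lambda)).

    Eigenvalues closer than the tie tolerance collapse into one jump, so
    N is strictly increasing across the returned rows.
    """
    xs = np.unique(s.eigenvalues)
    ns = counting_function(s, xs)
    keep = np.r_[True, np.diff(ns) > 0]
    return np.column_stack([xs[keep], ns[keep]])


def spectral_gaps(
    s: Spectrum,
    factor: float = 10.0,
    bulk: tuple[float, float] = (0.05, 0.90),
) -> list[tuple[float, float]]:
    """Flat steps of the counting function that are anomalously long.

    Gaps between consecutive distinct positive eigenvalues longer than
    ``factor`` times the median such gap are reported as (lo, hi)
    intervals.  Detection is restricted to steps whose counting-function
    height N lies in the ``bulk`` fraction of the spectrum: spacing at the
    spectral edges is dominated by extreme-eigenvalue statistics (in an
    Erdos-Renyi graph, by degree outliers), not by spectral structure.
    Fractal approximations (e.g. the Sierpinski gasket) report many bulk
    gaps; comparable random graphs report none.
    """
    xs = np.unique(s.eigenvalues)
    xs = xs[xs > EIG_TOL]
    if xs.size < 3:
        return []
    steps = np.diff(xs)
    thresh = factor * float(np.median(steps))
    lo, hi = bulk
    n = s.n
    out = []
    for i in np.nonzero(steps > thresh)[0]:
        height = int(np.searchsorted(s.eigenvalues, xs[i] + EIG_TOL, side="right"))
        if lo * n <= height <= hi * n:
            out.append((float(xs[i]), float(xs[i + 1])))
    return out


@dataclass(frozen=True)
class AlphaFit:
    """Power-law exponent of the counting function's growth.

    Ordinary least squares of log N(lambda_i) on log lambda_i over an
    index interval away from both spectral edges; ``alpha`` is the slope.
    """

    alpha: float
    r_squared: float
    interval: tuple[int, int]  # 1-based eigenvalue index range, inclusive
    n_points: int


def fit_alpha(
    s: Spectrum,
    interval: tuple[int, int] | None = None,
) -> AlphaFit:
    """Fit N(x) ~ const * x^alpha by log-log linear regression.

    ``interval`` is a 1-based inclusive eigenvalue index range; default is
    ceil(0.05 n) .. floor(0.95 n), which keeps the fit off both spectral
    edges.  Zero eigenvalues inside the interval are excluded.
    """
    n = s.n
    if interval is None:
        interval = (max(1, int(np.ceil(0.05 * n))), max(1, int(np.floor(0.95 * n))))
    lo, hi = interval
    if not 1 <= lo <= hi <= n:
        raise GraphError(f"invalid index interval {interval} for n={n}")
    lam = s.eigenvalues[lo - 1 : hi]
    pos = lam > EIG_TOL
    lam = lam[pos]
    if np.unique(lam).size < 3:
        raise GraphError("interval must contain >= 3 distinct positive eigenvalues")
    x = np.log(lam)
    y = np.log(counting_function(s, lam))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return AlphaFit(float(slope), r2, (lo, hi), int(lam.size))


def weyl_ratio(
    s: Spectrum,
    alpha: float | AlphaFit,
    grid: np.ndarray | int = 400,
) -> np.ndarray:
    """Sample W(x) = N(x) / x^alpha; rows (x, W(x)).

    ``grid`` is either explicit positive sample points or a point count
    for a log-spaced grid over [lambda_2, lambda_max] (the grid excludes 0
    by construction).
    """
    a = alpha.alpha if isinstance(alpha, AlphaFit) else float(alpha)
    if a <= 0:
        raise GraphError(f"alpha must be positive, got {a}")
    if np.isscalar(grid):
        pos = s.eigenvalues[s.eigenvalues > EIG_TOL]
        if pos.size < 2:
            raise GraphError("spectrum has too few positive eigenvalues")
        xs = np.geomspace(pos[0], pos[-1], int(grid))
    else:
        xs = np.asarray(grid, dtype=float)
        if (xs <= 0).any():
            raise GraphError("Weyl-ratio grid must exclude 0")
    w = counting_function(s, xs) / xs**a
    return np.column_stack([xs, w])


def eigen_projection(
    g: Graph,
    indices: tuple[int, ...] = (2, 3),
) -> dict:
    """Vertex coordinates in eigenfunction space.

    Uses eigenfunctions of the degree-normalized problem L f = lambda D f,
    mapped back so the first eigenfunction is constant; the plotted
    coordinates are (f_i(v), f_j(v)[, f_k(v)]) for 1-based eigenvalue
    indices i < j (< k), all >= 2 (the constant eigenfunction carries no
    information).  Per-vertex category tags pass through for colouring.

    Returns a dict with vertex labels, the coordinate array, the edge
    list, and categories.
    """
    if len(indices) not in (2, 3):
        raise GraphError("projection dimension must be 2 or 3")
    if any(i < 2 for i in indices):
        raise GraphError("projection indices must be >= 2 (index 1 is constant)")
    if len(set(indices)) != len(indices):
        raise GraphError("projection indices must be distinct")
    d = degrees(g)
    if (d == 0).any() or giant_component(g).n != g.n:
        raise GraphError("graph is disconnected: extract the giant component first")
    nl = normalized_laplacian(g)
    s = spectrum(nl)
    cols = [i - 1 for i in indices]
    coords = nl.back_transform(s.eigenfunctions[:, cols])
    return {
        "vertices": list(g.vertices),
        "coordinates": coords,
        "indices": tuple(indices),
        "edges": g.edge_list(),
        "categories": {v: g.categories.get(v) for v in g.vertices},
        "eigenvalues": s.eigenvalues[cols].tolist(),
    }
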