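# Methods

`selfsim` probes a network for two structural signatures: fractal-like
spectral self-similarity and Watts–Strogatz small-world organization. It
was built around the *C. elegans* connectome — an undirected, unweighted
graph combining chemical synapses and gap junctions — and around the
synthetic comparison graphs needed to interpret results on it: Erdős–Rényi
random graphs, random branching trees, graph approximations of the
Sierpinski gasket and the hexacarpet, and probabilistic rewirings.

## Graph model and Laplacians

A graph is simple and undirected, with an ordered list of string vertex
labels fixing all matrix indexing. Connectome assembly takes the directed
chemical-synapse count matrix `C` and the symmetric gap-junction matrix
`G`, forms `C + Cᵀ + G`, discards the diagonal, and binarizes: only the
skeleton of connectivity is retained. Analyses operate on the largest
connected component (for the worm, 279 of 302 neurons); size ties are
broken toward the component containing the smallest-indexed vertex.

The combinatorial Laplacian is `L = D − A` with `A` the 0/1 adjacency and
`D` the diagonal degree matrix: symmetric, positive semi-definite, row
sums zero, and the multiplicity of eigenvalue 0 equal to the number of
components. The degree-normalized form used for eigen-projection is the
symmetric `D^{-1/2} L D^{-1/2}`, whose spectrum lies in `[0, 2]` and which
shares eigenvalues with the generalized problem `L f = λ D f`; generalized
eigenvectors are recovered by multiplying symmetric ones by `D^{-1/2}`,
which makes the bottom eigenfunction constant. The symmetric convention
keeps a symmetric eigensolver (deterministic, numerically robust) while
being similar to the random-walk form `D^{-1} L`.

## Spectral statistics

Eigendecomposition is dense (`numpy.linalg.eigh`); graphs of interest have
at most a few thousand vertices, where dense solvers are faster and more
reproducible than iterative ones. Each eigenvector is sign-fixed so its
largest-magnitude entry is positive (first index on ties), making all
exported coordinates bit-reproducible. Inside a degenerate eigenspace the
basis remains solver-dependent; reports record multiplicities and no test
asserts individual vectors there.

The eigenvalue counting function is `N(x) = #{i : λ_i ≤ x + ε}` with tie
tolerance `ε = 1e-9` absorbing floating-point eigenvalue jitter. Spectral
gaps — flat steps of `N` — are reported when the spacing between
consecutive distinct positive eigenvalues exceeds 10× the median spacing
*and* the step's height `N` lies within the central 5–90 % of the
spectrum. The bulk restriction matters: spacing at the spectral edges is
governed by extreme-eigenvalue statistics (in a sparse random graph, the
top eigenvalues track the largest degrees and are widely spaced for that
reason alone), so edge gaps say nothing about self-similar structure.
Under this rule the level-5 gasket reports ~60 gaps and matched random
graphs report none over 40 seeds.

The counting function grows like `x^α` in the bulk; `α` is the slope of
an ordinary least-squares fit of `log N(λ_i)` against `log λ_i`. The
default fit window is eigenvalue indices `⌈0.05 n⌉ … ⌊0.95 n⌋`, excluding
zeros — wide enough to average over steps, off both spectral edges; the
window is configurable. The Weyl ratio `W(x) = N(x)/x^α` is sampled on a
log-spaced grid over `[λ₂, λ_n]` (never at 0): for exactly power-law
spectra it is constant; log-periodic oscillation of `W` is the classical
signature of spectral self-similarity on fractals.

Eigen-projection plots vertex `v` at `(f_i(v), f_j(v))` (or a 3-tuple) for
low, non-constant generalized eigenfunctions, default indices (2, 3) and
(2, 3, 4); per-vertex categories (e.g. sensory/motor/interneuron) pass
through for coloring. Which Laplacian feeds the counting-function and
Weyl analyses is selectable; the default is the un-normalized Laplacian,
with `--normalized` switching both.

## Small-world statistics

The clustering coefficient of a vertex with degree `k ≥ 2` and `e` edges
among its neighbours is `c = e / (k(k−1)/2)`; vertices with `k < 2` are
assigned `c = 0` and included in the average `C̄`. The inclusion
convention matters for sparse random graphs, where a ~9 % share of
degree-≤1 vertices at the connectome's density pulls `C̄` below `p`.
Neighbour-edge counts come from `diag(A³)/2`.

Path length is the hop count of a shortest path; all-pairs distances come
from per-source breadth-first search (Dijkstra with unit weights — the
two are verified equivalent in the tests), and `L̄` is the mean over
unordered reachable pairs. The small-world comparison generates, per
seed, a density-matched `G(n, p)` with `p = |E| / (n(n−1)/2)`; a
disconnected realization has `L̄` computed on its largest component and
is flagged. A network is called small-world when `C̄` is several-fold the
matched-random value while `L̄` stays within a modest factor (defaults 2×
each, configurable).

Note on the gasket benchmark: the level-5 gasket's `C̄ = 164.5/366 =
0.4495` follows from its degree census (3 corner vertices with `c = 1`,
243 with `c = 1/2`, 120 with `c = 1/3`) and is reproduced exactly. Its
`L̄` computes to 16.9244, confirmed against an independent shortest-path
oracle and consistent with the known asymptotic mean distance
`∼ (466/885)·2^m`.

## Energy, resistance, and localization

The energy of a vertex function is `E(f) = Σ_{{u,v}∈E} (f(u) − f(v))² =
fᵀLf`, the eigenvalue for a unit eigenfunction. Treating edges as unit
resistors, the effective resistance `R(u,v)` is computed either from the
harmonic function solving `L h = e_u − e_v` with one vertex grounded (any
grounding gives the same potential difference) or, for all pairs, from
one Laplacian pseudoinverse: `R(u,v) = L⁺_uu + L⁺_vv − 2 L⁺_uv`. `R` is a
metric bounded above by hop distance.

The spacial variance of a unit-norm function measures how tightly its
mass sits in the resistance metric:

    Var_c(f) = min_y Σ_x r(x, y)^c · f(x)²

with exponent `c` (default 1) and the minimizing vertex `y` recorded as
the function's center. Low variance means localization — mass confined
to a small resistance neighbourhood — which is characteristic of
eigenfunctions on fractal graphs and absent from comparable random
graphs. Two conventions make the statistic comparable across graphs:

* **Dimensionless resistance.** `r` is `R` divided by its mean over
  vertex pairs. Raw resistances carry the graph's global scale (an order
  of magnitude larger on the level-5 gasket than on its matched random
  graph), which would dominate any cross-graph comparison; the rescaled
  score asks what fraction of the graph's typical resistance span the
  function occupies. The raw scale remains available
  (`normalize_resistance=False`).
* **Eigenspace canonicalization.** Localization is a property of an
  eigenspace, not of the arbitrary orthonormal basis a dense solver
  returns inside a repeated eigenvalue — and on highly symmetric graphs
  this is almost the whole spectrum (94 % of the level-5 gasket's
  eigenvalues are degenerate, with multiplicities up to 120). Before
  scoring, each degenerate eigenspace is rotated by the orthogonal
  factor of a column-pivoted QR of its basis transpose (the
  selected-columns rotation used to build localized orbitals in
  electronic-structure methods): deterministic, span-preserving, and
  localization-revealing. Simple eigenvalues are untouched
  (`localize_eigenspaces=False` disables).

With these conventions the gasket's eigenfunctions are strongly
localized (median variance ≈ 0.20 at `c = 1`) versus ≈ 0.58 for matched
random graphs, a separation stable across seeds (rank-sum p ≪ 1e-10).

## Synthetic generators

All seeded generators use a single `numpy` PRNG stream per call; fractal
generators are fully deterministic with canonical geometric labelings.

* `random_gnp(n, p, seed)`: each of the `n(n−1)/2` pairs is an edge
  independently with probability `p`. The connectome-matched regime is
  `n ≈ 279–366`, `p ≈ 0.01–0.06`.
* `random_tree(n, B, seed)`: breadth-order branching; each branch point
  draws its child count uniformly from `{1,…,B}`, capped by the remaining
  vertex budget. Always a tree (`n−1` edges, max degree `≤ B+1`; `B = 1`
  is a path). The uniform child-count distribution is the simplest choice
  where no distribution is prescribed. Trees carry many leaves sharing a
  parent; each such pair contributes a leaf-difference eigenvector with
  Laplacian eigenvalue 1, so eigenvalue 1 appears with multiplicity at
  least (#leaves − #leaf-parents) — the mechanism behind the large
  vertical jump in tree counting functions.
* `sierpinski_gasket(m)`: level-0 is a triangle; level `m` glues three
  level-(m−1) copies at outer corners. `(3^{m+1}+3)/2` vertices,
  `3^{m+1}` edges; built on an integer lattice with lexicographic
  labeling. Level 5 (366 vertices, 729 edges) is the standard positive
  control for fractal spectral behaviour.
* `hexacarpet(m)`: the face-adjacency graph of the `m`-fold repeated
  barycentric subdivision of a triangle — `6^m` faces, adjacent when
  sharing an edge; level 1 is a 6-cycle. Exact rational coordinates make
  face identification robust. This face-adjacency construction is the
  published definition of the hexacarpet approximation.
* `rewire(g, p, seed)`: each edge is independently selected with
  probability `p`; a selected edge keeps its lower-indexed endpoint and
  moves the other to a uniform non-neighbour. Edge count and simplicity
  are invariant; a vertex adjacent to all others skips its rewire.
* `matched_random(g, seed)`: `G(n, p)` at `g`'s density, the null model
  for the small-world comparison.

## What the synthetic data does and does not show

The generators reproduce the *structural conditions* of the study —
vertex counts, densities, fractal gluing, bounded branching — so every
pipeline stage can be exercised and checked against closed forms
(clustering census, vertex/edge counts, binomial edge statistics,
power-law exponent recovery). They do not emulate biological features of
a real connectome: degree heterogeneity beyond `G(n,p)`, neuron-type
assortativity, spatial embedding, or synapse multiplicities (discarded by
design). Passing tests therefore validate the measurements, not any
biological claim about a particular network.

## Numerical choices and limitations

* Eigenvalue comparisons use absolute tolerance 1e-9; orthonormality and
  identity checks 1e-8; degeneracy grouping 1e-8.
* All-pairs resistance uses one `n×n` pseudoinverse rather than `n²`
  solves; dense methods cap practical size at a few thousand vertices.
* Problem sizes in the test and benchmark suites: gaskets to level 5-6
  (up to ~1100 vertices), random-graph batteries at n ≤ 40 with 10-100
  replicates, 25-seed matched-random panels — sizes at which every
  quantity is exactly or statistically checkable.
* The matched-random path-length convention (largest component, flagged)
  is one of several possible treatments of disconnected realizations;
  reported values depend on it at connectome-like densities.
* Gap detection thresholds (10× median spacing, 5–90 % bulk) are
  heuristics chosen to separate known-fractal from random spectra; very
  small graphs (< ~20 distinct eigenvalues) give unreliable gap reports.
* The rewiring rule fixes the lower-indexed endpoint, which preserves
  edge count but is not degree-preserving (unlike double-edge swaps);
  this matches the simpler rule the analysis calls for.
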