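# selfsim

A spectral-graph toolbox for probing networks for fractal self-similarity
and small-world structure, built for connectome-scale graphs (hundreds to
a few thousand vertices).

Motivated by the *C. elegans* nervous system — 302 neurons whose chemical
synapses and gap junctions combine into one undirected, unweighted graph
with a 279-neuron giant component — the package asks a structural
question: is a given network organized like a fractal, like a random
graph, like a tree, or like a small world? It answers by comparing the
network against synthetic controls it can generate itself: Erdős–Rényi
graphs `G(n, p)`, random branching trees, level-`m` approximations of the
Sierpinski gasket and the hexacarpet, and probabilistic rewirings.

## What it computes

For a graph `G` with Laplacian `L = D − A`:

* **Eigenvalue counting function** `N(x) = #{i : λᵢ ≤ x}` and its
  spectral gaps — flat steps of `N`, the fingerprint of fractal spectra.
* **Weyl ratio** `W(x) = N(x)/x^α`, with `α` fitted by log–log least
  squares on the bulk of the spectrum; log-periodic oscillation of `W`
  signals spectral self-similarity.
* **Eigen-projection**: vertex coordinates `(f₂(v), f₃(v)[, f₄(v)])` from
  low eigenfunctions of the degree-normalized problem `Lf = λDf`, for
  spectral drawings colored by vertex category.
* **Small-world statistics**: per-vertex and average clustering
  coefficient `C̄`, all-pairs shortest-path length `L̄`, and the
  Watts–Strogatz comparison against density-matched random graphs.
* **Localization**: graph energy `E(f) = fᵀLf`, effective resistances via
  harmonic functions / the Laplacian pseudoinverse, and the spacial
  variance `Var_c(f) = min_y Σₓ r(x,y)^c f(x)²` of every eigenfunction —
  low variance means a localized eigenfunction, a fractal-like signature.

Connectome assembly from raw matrices (`C + Cᵀ + G_gap`, binarized,
diagonal dropped), giant-component extraction, and readers/writers for
edge-list TSV, adjacency CSV, GraphML, and Matrix Market are included.
See `docs/methods.md` for conventions and assumptions.

## Worked example

```python
import numpy as np
import selfsim as ss

g = ss.sierpinski_gasket(5)            # 366 vertices, 729 edges
s = ss.spectrum(ss.laplacian(g))

fit = ss.fit_alpha(s)
print(f"alpha {fit.alpha:.4f}, gaps {len(ss.spectral_gaps(s))}")

rep = ss.small_world_report(g, seeds=range(25))
print(f"C {rep.clustering_avg:.4f}  L {rep.path_length_avg:.4f}  "
      f"C_rand {rep.random_clustering_avg:.4f}  small world: {rep.is_small_world()}")

var = np.median([r.variance for r in ss.variance_distribution(g)])
print(f"median spacial variance {var:.4f}")
```

prints

```
alpha 0.9419, gaps 60
C 0.4495  L 16.9244  C_rand 0.0097  small world: False
median spacial variance 0.1958
```

The gasket's counting function shows 60 spectral gaps (a random graph of
the same size and density shows none), its clustering is ~46× its
matched-random value but its path length is ~3.9× longer — high
clustering alone does not make a small world — and its eigenfunctions
are strongly localized (median variance 0.20 vs 0.59 for the matched
random graph). Rewiring 20 % of its edges (`ss.rewire(g, 0.2, seed=0)`)
collapses the path length to 5.47 while clustering stays 24× random:
the rewired fractal is small-world.

The same pipeline runs end to end from the shell:

```
selfsim generate --kind gasket --level 5 --out gasket.edgelist
selfsim spectrum   --input gasket.edgelist --out spec/
selfsim smallworld --input gasket.edgelist --reps 25 --out sw/
selfsim localize   --input gasket.edgelist --out loc/
```

and on real data, `selfsim assemble --chem chem.csv --gap gap.csv --out
net.edgelist` builds the combined connectome graph from a directed
chemical-synapse count matrix and a symmetric gap-junction matrix, after
which the `spectrum`/`smallworld`/`localize` subcommands (and `selfsim
run --config cfg.json` for the full pipeline) apply unchanged.

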