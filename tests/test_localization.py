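import numpy as np
import pytest

import selfsim as ss
from selfsim.graph_core import Graph, GraphError
from selfsim.localization import localized_eigenspace_basis


class TestGraphEnergy:
    def test_constant_function_has_zero_energy(self, k3):
        assert ss.graph_energy(k3, np.full(3, 2.5)) == 0.0

    def test_single_edge_unit_step(self):
        g = Graph.from_edges("ab", [("a", "b")])
        assert ss.graph_energy(g, np.array([1.0, 0.0])) == 1.0

    def test_unit_eigenfunction_energy_equals_eigenvalue(self, gasket5, gasket5_spectrum):
        s = gasket5_spectrum
        for i in [1, 50, 200, 365]:
            e = ss.graph_energy(gasket5, s.eigenfunctions[:, i])
            assert e == pytest.approx(float(s.eigenvalues[i]), abs=1e-8)

    def test_dimension_mismatch_rejected(self, k3):
        with pytest.raises(GraphError):
            ss.graph_energy(k3, np.zeros(5))


class TestEffectiveResistance:
    def test_single_edge(self):
        g = Graph.from_edges("ab", [("a", "b")])
        assert ss.effective_resistance(g, "a", "b") == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3, 7])
    def test_path_series_rule(self, k):
        labels = [str(i) for i in range(k + 1)]
        g = Graph.from_edges(labels, [(str(i), str(i + 1)) for i in range(k)])
        assert ss.effective_resistance(g, "0", str(k)) == pytest.approx(k, abs=1e-9)

    def test_triangle_parallel_combination(self, k3):
        # 1 ohm in parallel with 1+1 ohms: 2/3
        assert ss.effective_resistance(k3, "a", "b") == pytest.approx(2 / 3)

    def test_disconnected_pair_raises(self):
        g = Graph.from_edges("abcd", [("a", "b"), ("c", "d")])
        with pytest.raises(GraphError, match="resistance"):
            ss.effective_resistance(g, "a", "c")

    def test_grounding_choice_irrelevant(self, k3):
        # harmonic solve grounds at the sink; compare against the
        # pseudoinverse route, which grounds nothing
        R = ss.resistance_matrix(k3)
        idx = k3.index()
        for u, v in [("a", "b"), ("b", "c")]:
            assert ss.effective_resistance(k3, u, v) == pytest.approx(
                R[idx[u], idx[v]], abs=1e-12
            )

    def test_matrix_matches_harmonic_solve_oracle_on_random_graphs(self):
        from conftest import random_graph_cases

        rng = np.random.default_rng(0)
        for g in random_graph_cases(30, seed=21):
            R = ss.resistance_matrix(g)
            idx = g.index()
            # spot-check a few pairs per graph against the linear solve
            for _ in range(3):
                u, v = rng.choice(g.vertices, 2, replace=False)
                assert R[idx[u], idx[v]] == pytest.approx(
                    ss.effective_resistance(g, u, v), abs=1e-8
                )

    def test_metric_and_dominated_by_hop_distance(self):
        from conftest import random_graph_cases

        for g in random_graph_cases(10, seed=33):
            R = ss.resistance_matrix(g)
            d = ss.shortest_paths(g).distances
            assert (R <= d + 1e-9).all()
            assert (R[:, None, :] <= R[:, :, None] + R[None, :, :] + 1e-9).all()


class TestSpacialVariance:
    def test_indicator_function_has_zero_variance(self, k3):
        res = ss.spacial_variance(k3, np.array([1.0, 0.0, 0.0]))
        assert res.variance == pytest.approx(0.0, abs=1e-12)
        assert res.center == "a"

    def test_invariant_under_sign_flip(self, k3):
        f = np.array([0.5, 0.5, -np.sqrt(0.5)])
        a = ss.spacial_variance(k3, f)
        b = ss.spacial_variance(k3, -f)
        assert a.variance == b.variance and a.center == b.center

    def test_unnormalized_input_normalized_internally(self, k3):
        f = np.array([2.0, 0.0, 0.0])
        assert ss.spacial_variance(k3, f).variance == pytest.approx(0.0, abs=1e-12)

    def test_invalid_exponent_rejected(self, k3):
        with pytest.raises(GraphError):
            ss.spacial_variance(k3, np.array([1.0, 0, 0]), c=0.0)

    def test_invariant_under_vertex_relabeling(self):
        rng = np.random.default_rng(4)
        g = ss.giant_component(ss.random_gnp(20, 0.3, 8))
        perm = rng.permutation(g.n)
        relabeled = Graph.from_edges(
            [g.vertices[i] for i in perm],
            [(u, v) for u, v in g.edge_list()],
        )
        a = sorted(r.variance for r in ss.variance_distribution(g))
        b = sorted(r.variance for r in ss.variance_distribution(relabeled))
        assert np.allclose(a, b, atol=1e-8)


class TestVarianceDistribution:
    def test_triangle_eigenspace_symmetry(self, k3):
        # individual variances inside a degenerate eigenspace depend on
        # the basis; the basis-averaged variance about any center is a
        # trace of the eigenspace projector and, by the triangle's
        # vertex-transitivity, identical for every center: tr = 4/3
        # (normalized r = 1 off-diagonal), i.e. 2/3 per function
        res = ss.variance_distribution(k3)
        assert len(res) == 2
        assert all(r.variance >= 0 for r in res)
        s = ss.spectrum(ss.laplacian(k3))
        B = s.eigenfunctions[:, 1:]  # eigenvalue-3 eigenspace
        R = ss.resistance_matrix(k3)
        r = R / R[np.triu_indices(3, 1)].mean()
        per_center_trace = r.T @ (B**2).sum(axis=1)
        assert np.allclose(per_center_trace, 4 / 3, atol=1e-9)

    def test_energies_equal_eigenvalues(self):
        g = ss.sierpinski_gasket(2)
        for r in ss.variance_distribution(g):
            assert r.energy == pytest.approx(r.eigenvalue, abs=1e-8)
        for r in ss.variance_distribution(g, normalized=True):
            assert r.energy == pytest.approx(r.eigenvalue, abs=1e-8)

    def test_deterministic(self):
        g = ss.sierpinski_gasket(2)
        a = [r.variance for r in ss.variance_distribution(g)]
        b = [r.variance for r in ss.variance_distribution(g)]
        assert a == b

    def test_localized_rotation_preserves_span_and_orthonormality(self):
        g = ss.sierpinski_gasket(3)
        s = ss.spectrum(ss.laplacian(g))
        lam = s.eigenvalues
        group = np.nonzero(np.abs(lam - 3.0) < 1e-8)[0]
        assert group.size > 1
        B = s.eigenfunctions[:, group]
        F = localized_eigenspace_basis(B)
        assert np.allclose(F.T @ F, np.eye(group.size), atol=1e-9)
        # same span: projectors agree
        assert np.allclose(F @ F.T, B @ B.T, atol=1e-9)
        # rotated functions are still eigenfunctions
        lap = ss.laplacian(g)
        assert np.allclose(lap @ F, 3.0 * F, atol=1e-8)

    def test_disconnected_graph_rejected(self):
        g = Graph.from_edges("abcd", [("a", "b"), ("c", "d")])
        with pytest.raises(GraphError):
            ss.variance_distribution(g)
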