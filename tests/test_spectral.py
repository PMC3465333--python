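import numpy as np
import pytest

import selfsim as ss
from selfsim.graph_core import Graph, GraphError
from selfsim.spectral import AlphaFit, Spectrum


def synthetic_spectrum(eigenvalues):
    lam = np.asarray(eigenvalues, dtype=float)
    return Spectrum(lam, np.eye(lam.size))


class TestSpectrum:
    def test_triangle(self, k3):
        s = ss.spectrum(ss.laplacian(k3))
        assert np.allclose(s.eigenvalues, [0, 3, 3], atol=1e-12)

    def test_star_on_four_vertices(self, star4):
        # char poly of the star Laplacian factors as x(x-1)^2(x-4)
        s = ss.spectrum(ss.laplacian(star4))
        assert np.allclose(s.eigenvalues, [0, 1, 1, 4], atol=1e-12)

    def test_disconnected_zero_multiplicity(self):
        g = Graph.from_edges(
            "abcdef",
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
        )
        s = ss.spectrum(ss.laplacian(g))
        assert int((np.abs(s.eigenvalues) < 1e-9).sum()) == 2

    def test_orthonormal_eigenfunctions(self, gasket5_spectrum):
        v = gasket5_spectrum.eigenfunctions
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(GraphError, match="symmetric"):
            ss.spectrum(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_sign_convention_deterministic(self, gasket5):
        a = ss.spectrum(ss.laplacian(gasket5))
        b = ss.spectrum(ss.laplacian(gasket5))
        assert np.array_equal(a.eigenfunctions, b.eigenfunctions)
        for j in range(a.n):
            col = a.eigenfunctions[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestCountingFunction:
    def test_triangle_values(self, k3):
        s = ss.spectrum(ss.laplacian(k3))
        assert ss.counting_function(s, 2.0) == 1
        assert ss.counting_function(s, 3.0) == 3

    def test_star_at_one(self, star4):
        s = ss.spectrum(ss.laplacian(star4))
        assert ss.counting_function(s, 1.0) == 3

    def test_reaches_n_at_spectral_top(self, gasket5_spectrum):
        s = gasket5_spectrum
        assert ss.counting_function(s, float(s.eigenvalues[-1])) == s.n
        assert ss.counting_function(s, -0.1) == 0

    def test_curve_is_nondecreasing(self, gasket5_spectrum):
        curve = ss.counting_curve(gasket5_spectrum)
        assert (np.diff(curve[:, 1]) > 0).all()


class TestSpectralGaps:
    def test_gasket_reports_gaps(self, gasket5_spectrum):
        assert len(ss.spectral_gaps(gasket5_spectrum)) > 0

    def test_matched_random_reports_none(self, gasket5):
        for seed in range(3):
            rg = ss.giant_component(ss.matched_random(gasket5, seed)[0])
            s = ss.spectrum(ss.laplacian(rg))
            assert ss.spectral_gaps(s) == []


class TestAlphaFit:
    def test_recovers_square_root_growth_exactly(self):
        # lambda_i = (i/n)^2 means N(x) = n sqrt(x): alpha = 1/2
        n = 200
        s = synthetic_spectrum(((np.arange(n) + 1) / n) ** 2)
        fit = ss.fit_alpha(s)
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_recovers_linear_growth_exactly(self):
        n = 200
        s = synthetic_spectrum((np.arange(n) + 1) / n)
        assert ss.fit_alpha(s).alpha == pytest.approx(1.0, abs=1e-6)

    def test_path_graph_has_one_dimensional_growth(self):
        # lambda_k = 2 - 2cos(pi k / n) ~ (pi k / n)^2, so N(x) ~ x^(1/2)
        n = 100
        path = Graph.from_edges(
            [str(i) for i in range(n)],
            [(str(i), str(i + 1)) for i in range(n - 1)],
        )
        s = ss.spectrum(ss.laplacian(path))
        fit = ss.fit_alpha(s, (10, 90))
        assert fit.alpha == pytest.approx(0.5, abs=0.1)

    def test_degenerate_interval_rejected(self, k3):
        s = ss.spectrum(ss.laplacian(k3))
        with pytest.raises(GraphError):
            ss.fit_alpha(s, (1, 3))  # only one distinct positive eigenvalue


class TestWeylRatio:
    def test_constant_for_exact_power_law(self):
        n, alpha = 300, 0.7
        s = synthetic_spectrum(((np.arange(n) + 1) / n) ** (1 / alpha))
        w = ss.weyl_ratio(s, alpha, grid=s.eigenvalues)
        assert np.allclose(w[:, 1], n * np.ones(n), rtol=1e-6)

    def test_triangle_value_at_three(self, k3):
        s = ss.spectrum(ss.laplacian(k3))
        w = ss.weyl_ratio(s, 1.0, grid=np.array([3.0]))
        assert w[0, 1] == pytest.approx(1.0)

    def test_decreasing_between_jumps(self, gasket5_spectrum):
        s = gasket5_spectrum
        lam = np.unique(s.eigenvalues)
        x = np.linspace(lam[5] + 1e-6, lam[6] - 1e-6, 10)  # inside one step
        w = ss.weyl_ratio(s, 0.8, grid=x)
        assert (np.diff(w[:, 1]) < 0).all()

    def test_grid_excluding_zero_enforced(self, k3):
        s = ss.spectrum(ss.laplacian(k3))
        with pytest.raises(GraphError):
            ss.weyl_ratio(s, 1.0, grid=np.array([0.0, 1.0]))


class TestEigenProjection:
    def test_path_coordinates_antisymmetric(self, path3):
        proj = ss.eigen_projection(path3, (2, 3))
        x = proj["coordinates"][:, 0]
        assert x[0] == pytest.approx(-x[2], abs=1e-9)

    def test_generalized_orthogonality_to_constants(self, gasket5):
        proj = ss.eigen_projection(gasket5, (2, 3, 4))
        d = ss.degrees(gasket5)
        for j in range(3):
            assert proj["coordinates"][:, j] @ d == pytest.approx(0.0, abs=1e-8)

    def test_cycle_projects_to_circle(self):
        c6 = Graph.from_edges(
            "123456", [(str(i), str(i % 6 + 1)) for i in range(1, 7)]
        )
        proj = ss.eigen_projection(c6, (2, 3))
        radii = np.linalg.norm(proj["coordinates"], axis=1)
        assert np.allclose(radii, radii[0], atol=1e-8)

    def test_disconnected_graph_instructs_giant_component(self):
        g = Graph.from_edges("abcd", [("a", "b"), ("c", "d")])
        with pytest.raises(GraphError, match="giant"):
            ss.eigen_projection(g)

    def test_repeated_runs_bit_identical(self, gasket5):
        a = ss.eigen_projection(gasket5, (2, 3))
        b = ss.eigen_projection(gasket5, (2, 3))
        assert np.array_equal(a["coordinates"], b["coordinates"])
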