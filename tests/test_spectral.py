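"""Spectral decomposition, diffusion geometry and relaxation time."""

import numpy as np
import pytest

from diffwalk import (
    DiffusionMap,
    RelaxationUndefinedError,
    UndirectedGraph,
    presence_field,
    spectral_decomposition,
    transition_matrix,
    truncation_error,
)
from diffwalk.spectral import eigenvalue_power


class TestDecomposition:
    def test_triangle_spectrum(self, triangle):
        m = spectral_decomposition(triangle, 3)
        assert np.allclose(sorted(m.eigenvalues_), [-0.5, -0.5, 1.0], atol=1e-10)

    def test_p4_spectrum(self, p4):
        m = spectral_decomposition(p4, 4)
        # walk spectrum of the path: cos(k*pi/3)
        assert np.allclose(sorted(m.eigenvalues_), [-1.0, -0.5, 0.5, 1.0], atol=1e-10)

    def test_stationary_pair_and_biorthogonality(self, random_graph_factory):
        g = random_graph_factory(80, 4.0, seed=2)
        m = spectral_decomposition(g, 80)
        assert np.allclose(m.psi_[:, 0], 1.0)
        assert np.allclose(m.phi_[:, 0], g.degrees / (2 * g.n_edges))
        assert np.abs(m.phi_.T @ m.psi_ - np.eye(80)).max() < 1e-8
        assert np.all(np.abs(m.eigenvalues_) <= 1.0)
        # eigen-relation T psi = psi Lambda, column by column
        t = transition_matrix(g).T.toarray()
        assert np.abs(t @ m.psi_ - m.psi_ * m.eigenvalues_).max() < 1e-8

    def test_truncated_matches_leading_full_modes(self, random_graph_factory):
        g = random_graph_factory(50, 4.0, seed=9)
        full = spectral_decomposition(g, 50)
        trunc = spectral_decomposition(g, 5)
        assert np.allclose(trunc.eigenvalues_, full.eigenvalues_[:5], atol=1e-8)

    def test_k_out_of_range_errors(self, triangle):
        with pytest.raises(ValueError, match="n_components"):
            spectral_decomposition(triangle, 4)

    def test_sparse_solver_agrees_with_dense(self, random_graph_factory):
        g = random_graph_factory(150, 4.0, seed=4)
        dense = DiffusionMap(n_components=10, dense_cutoff=2000).fit(g)
        sparse = DiffusionMap(n_components=10, dense_cutoff=10).fit(g)
        assert np.allclose(sparse.eigenvalues_, dense.eigenvalues_, atol=1e-8)
        assert np.abs(np.abs(sparse.psi_) - np.abs(dense.psi_)).max() < 1e-6


class TestCoordinates:
    def test_t0_is_psi_and_column0_constant(self, lollipop):
        m = spectral_decomposition(lollipop, 4)
        x0 = m.coordinates(0)
        assert np.allclose(x0, m.psi_)
        for t in (0, 1, 7, 100):
            assert np.allclose(m.coordinates(t)[:, 0], 1.0)

    def test_long_time_collapse_to_stationary_axis(self, triangle):
        m = spectral_decomposition(triangle, 3)
        x = m.coordinates(200)
        assert np.allclose(x, np.tile([1.0, 0, 0], (3, 1)), atol=1e-12)

    def test_negative_time_errors(self, triangle):
        m = spectral_decomposition(triangle, 3)
        with pytest.raises(ValueError):
            m.coordinates(-1)


class TestDiffusionDistance:
    def test_identity_and_symmetry(self, triangle):
        m = spectral_decomposition(triangle, 3)
        assert m.diffusion_distance(0, 0, 3) == 0.0
        # vertex transitivity of K3
        for t in (0, 1, 2, 5):
            d01 = m.diffusion_distance(0, 1, t)
            assert d01 == pytest.approx(m.diffusion_distance(0, 2, t))
            assert d01 == pytest.approx(m.diffusion_distance(1, 2, t))

    def test_triangle_closed_form(self, triangle):
        m = spectral_decomposition(triangle, 3)
        # direct weighted-l2 between one-step fields: sqrt(1.5)
        assert m.diffusion_distance(0, 1, 1) == pytest.approx(np.sqrt(1.5), abs=1e-10)

    def test_equals_weighted_l2_between_presence_fields(self, random_graph_factory):
        g = random_graph_factory(40, 4.0, seed=5)
        m = spectral_decomposition(g, 40)
        w = 2.0 * g.n_edges / g.degrees
        for t in (1, 3, 10):
            p0 = m.presence_field(3, t)
            p1 = m.presence_field(17, t)
            direct = np.sqrt(np.sum((p0 - p1) ** 2 * w))
            assert m.diffusion_distance(3, 17, t) == pytest.approx(direct, abs=1e-8)


class TestPresenceField:
    def test_p4_one_and_two_steps(self, p4):
        m = spectral_decomposition(p4, 4)
        p, mass = presence_field(m, 0, 1)
        assert np.allclose(p, [0, 1, 0, 0], atol=1e-10)
        assert mass == pytest.approx(1.0)
        p, _ = presence_field(m, 0, 2)
        assert np.allclose(p, [0.5, 0, 0.5, 0], atol=1e-10)

    def test_lollipop_stationary_limit(self, lollipop):
        m = spectral_decomposition(lollipop, 4)
        for i in range(4):
            p, _ = presence_field(m, i, 10**6)
            assert np.allclose(p, [0.25, 0.25, 0.375, 0.125], atol=1e-9)

    def test_truncated_mass_conserved_at_any_rank(self, random_graph_factory):
        # sum_j phi_k(j) = delta_k0 by biorthogonality with psi_0 = 1, so
        # every truncation conserves probability mass exactly
        g = random_graph_factory(40, 4.0, seed=8)
        for K in (5, 20, 40):
            m = spectral_decomposition(g, K)
            _, mass = presence_field(m, 0, 3)
            assert mass == pytest.approx(1.0, abs=1e-10)


class TestRelaxationTime:
    def test_complete_graphs(self, triangle, k4):
        assert spectral_decomposition(triangle, 3).relaxation_time() == pytest.approx(2.0)
        assert spectral_decomposition(k4, 4).relaxation_time() == pytest.approx(1.5)

    def test_bipartite_error_names_cause(self, p4):
        m = spectral_decomposition(p4, 4)
        with pytest.raises(RelaxationUndefinedError, match="bipartite"):
            m.relaxation_time()


class TestEigenvaluePower:
    def test_signs_and_underflow(self):
        lam = np.array([1.0, -0.5, 0.5, 0.0])
        assert np.allclose(eigenvalue_power(lam, 0), 1.0)
        assert np.allclose(eigenvalue_power(lam, 3), [1.0, -0.125, 0.125, 0.0])
        huge = eigenvalue_power(np.array([-0.999]), 10**6)
        assert huge[0] == 0.0  # graceful underflow, even sign

    def test_matches_naive_power(self):
        lam = np.linspace(-1, 1, 11)
        for t in (1, 2, 5, 17):
            assert np.allclose(eigenvalue_power(lam, t), lam**t, atol=1e-12)


class TestTruncationError:
    def test_full_rank_is_exact(self, random_graph_factory):
        g = random_graph_factory(40, 4.0, seed=6)
        assert truncation_error(g, 40, 5) < 1e-10

    def test_cap_guard(self, random_graph_factory):
        g = random_graph_factory(30, 4.0, seed=6)
        with pytest.raises(ValueError, match="cap"):
            truncation_error(g, 10, 2, cap=10)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, lollipop):
        m = spectral_decomposition(lollipop, 4)
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = DiffusionMap.load(path)
        assert np.array_equal(m.eigenvalues_, m2.eigenvalues_)
        assert np.array_equal(m.psi_, m2.psi_)
        assert np.array_equal(m.phi_, m2.phi_)
        assert m2.relaxation_time() == pytest.approx(m.relaxation_time())
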