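import warnings

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lrrwind import (
    RunConfig,
    SolenoidSpec,
    annotate_structure,
    eigen_winding,
    laplacian_eigenbasis,
    make_solenoid,
    mutual_knn_graph,
    phase_estimate,
    phase_pipeline,
    sliding_window_embed,
    swl2d,
)
from lrrwind.spectral import SpectralBasis

from conftest import unwrapped_angle_winding


class TestSlidingWindowEmbed:
    def test_default_embedding_dimension_is_75(self):
        sig = np.random.default_rng(0).normal(size=(100, 3))
        emb = sliding_window_embed(sig, window=24, delay=1)
        assert emb.points.shape == (100 - 24, 75)

    def test_zero_window_is_identity(self):
        sig = np.random.default_rng(1).normal(size=(30, 3))
        emb = sliding_window_embed(sig, window=0, delay=1)
        np.testing.assert_array_equal(emb.points, sig)

    def test_periodic_tangents_embed_onto_a_planar_ellipse(self):
        t = np.arange(300)
        sig = np.column_stack(
            [np.cos(2 * np.pi * t / 24), np.sin(2 * np.pi * t / 24),
             np.zeros(300)]
        )
        emb = sliding_window_embed(sig, window=24, delay=1)
        centered = emb.points - emb.points.mean(axis=0)
        eigvals = np.linalg.eigvalsh(centered.T @ centered)[::-1]
        assert eigvals[:2].sum() / eigvals.sum() >= 0.99

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_embed(np.zeros((20, 3)), window=24)


class TestMutualKnnGraph:
    def test_three_collinear_points_tie_rule(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        graph = mutual_knn_graph(pts, k=1)
        # middle point's single neighbor is its left one under the tie rule,
        # so only (0, 1) is mutual
        degrees = [graph.degree[i] for i in range(3)]
        assert graph.has_edge(0, 1)
        assert degrees == [1, 1, 0]

    def test_circle_gives_cycle_graph(self):
        t = np.arange(12)
        pts = np.column_stack(
            [np.cos(2 * np.pi * t / 12), np.sin(2 * np.pi * t / 12)]
        )
        graph = mutual_knn_graph(pts, k=2)
        assert all(graph.degree[i] == 2 for i in range(12))
        assert nx.is_connected(graph)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    def test_mutual_graph_is_subgraph_of_union_graph(self, seed, k):
        pts = np.random.default_rng(seed).normal(size=(30, 4))
        mutual = mutual_knn_graph(pts, k=k, mutual=True)
        union = mutual_knn_graph(pts, k=k, mutual=False)
        assert all(union.has_edge(*e) for e in mutual.edges)

    def test_k_out_of_range_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            mutual_knn_graph(pts, k=5)


class TestLaplacianEigenbasis:
    def test_cycle_graph_closed_form_spectrum(self):
        n = 20
        graph = nx.cycle_graph(n)
        basis = laplacian_eigenbasis(graph, n_vecs=8)
        analytic = np.sort(2 - 2 * np.cos(2 * np.pi * np.arange(n) / n))[:8]
        np.testing.assert_allclose(basis.eigenvalues, analytic, atol=1e-8)

    def test_connected_graph_has_single_constant_kernel_vector(self):
        graph = nx.random_regular_graph(4, 30, seed=1)
        basis = laplacian_eigenbasis(graph, n_vecs=6)
        assert np.sum(basis.eigenvalues < 1e-10) == 1
        kernel = basis.eigenvectors[:, 0]
        assert np.std(kernel) / abs(np.mean(kernel)) < 1e-6

    def test_eigenvectors_orthonormal(self):
        graph = nx.cycle_graph(25)
        basis = laplacian_eigenbasis(graph, n_vecs=8)
        gram = basis.eigenvectors.T @ basis.eigenvectors
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-8)

    def test_disconnected_graph_warns_and_keeps_largest_component(self):
        graph = nx.union(nx.cycle_graph(20), nx.cycle_graph(5), rename=("a", "b"))
        graph = nx.convert_node_labels_to_integers(graph)
        with pytest.warns(UserWarning, match="disconnected"):
            basis = laplacian_eigenbasis(graph, n_vecs=4)
        assert len(basis.node_ids) == 20


class TestPhaseEstimate:
    @staticmethod
    def _basis_from_angles(phi):
        vecs = np.column_stack([np.cos(phi), np.sin(phi)])
        return SpectralBasis(
            eigenvalues=np.array([0.1, 0.2]),
            eigenvectors=vecs,
            selected_pair=(0, 1),
            node_ids=np.arange(len(phi)),
        )

    def test_recovers_angles_wrapped(self):
        phi = np.linspace(-3.0, 3.0, 50)
        track = phase_estimate(self._basis_from_angles(phi))
        np.testing.assert_allclose(track.theta, phi, atol=1e-12)

    def test_sign_flip_reflects_phase(self):
        phi = np.linspace(0.1, 2.9, 40)
        basis = self._basis_from_angles(phi)
        flipped = SpectralBasis(
            basis.eigenvalues, basis.eigenvectors * [1, -1],
            basis.selected_pair, basis.node_ids,
        )
        track = phase_estimate(basis)
        reflected = phase_estimate(flipped)
        np.testing.assert_allclose(reflected.theta, -track.theta, atol=1e-12)
        assert np.all(np.diff(np.unwrap(reflected.theta)) < 0)


class TestEigenWinding:
    def test_clean_revolutions_counted(self):
        t = np.arange(300)
        phi = 2 * np.pi * 6 * t / 300
        basis = TestPhaseEstimate._basis_from_angles(phi)
        profile = eigen_winding(basis)
        assert profile.w[0] == 0.0
        assert profile.source_kind == "laplacian"
        assert profile.w[-1] == pytest.approx(6.0, abs=0.25)
        oracle = np.abs(
            unwrapped_angle_winding(basis.eigenvectors[:, :2])
        )
        assert np.max(np.abs(profile.w[8:-8] - oracle[8:-8])) < 0.05


class TestSwl2d:
    def test_linear_profile_scores_zero(self):
        w = 0.04 * np.arange(200)
        result = swl2d(w, window=24)
        np.testing.assert_allclose(result.scores, 0.0, atol=1e-10)
        assert result.spike_intervals == ()

    def test_plateau_spike_located(self):
        w = np.concatenate(
            [np.arange(1, 121) / 24.0, np.full(10, 5.0),
             5.0 + np.arange(1, 121) / 24.0]
        )
        result = swl2d(w, window=24)
        peak = result.centers[np.argmax(result.scores)]
        assert 120 - 12 <= peak <= 130 + 12
        assert any(lo <= peak <= hi for lo, hi in result.spike_intervals)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(4)
        w = np.cumsum(rng.normal(0.04, 0.05, 150))
        a = swl2d(w, window=24)
        b = swl2d(w + 17.3, window=24)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-9)


class TestSolenoidPhase:
    @pytest.mark.parametrize("period", [20, 24, 28])
    def test_eigenvector_frequency_matches_coil_period(self, period):
        curve, _ = make_solenoid(SolenoidSpec(turns=10, period=period))
        result = annotate_structure(curve)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = phase_pipeline(curve, result.annotation)
        n = len(ph.basis.node_ids)
        expected = n / period
        for col in ph.basis.selected_pair:
            vec = ph.basis.eigenvectors[:, col]
            freq = np.argmax(np.abs(np.fft.rfft(vec - vec.mean()))[1:]) + 1
            assert abs(freq - expected) <= 1.0

    @pytest.mark.parametrize("period", [20, 24, 28])
    def test_eigenvector_pair_in_quadrature(self, period):
        curve, _ = make_solenoid(SolenoidSpec(turns=10, period=period))
        result = annotate_structure(curve)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = phase_pipeline(curve, result.annotation)
        x = ph.basis.eigenvectors[:, ph.basis.selected_pair[0]]
        y = ph.basis.eigenvectors[:, ph.basis.selected_pair[1]]
        xc = np.correlate(x - x.mean(), y - y.mean(), "full")
        lag = abs(int(np.argmax(np.abs(xc))) - (len(x) - 1))
        assert abs(lag - period / 4) <= period / 8

    def test_phase_increment_matches_coil_rate(self):
        curve, _ = make_solenoid(SolenoidSpec(turns=10, period=24))
        result = annotate_structure(curve)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = phase_pipeline(curve, result.annotation)
        increments = np.diff(np.unwrap(ph.phase.theta))
        mean_rate = abs(np.mean(increments))
        assert mean_rate == pytest.approx(2 * np.pi / 24, rel=0.15)
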