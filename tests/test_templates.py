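"""Template construction: closed-form spectra against numerical oracles."""

import numpy as np
import pytest

from specmatch import templates as tp


class TestCirculant:
    def test_alpha_zero_is_identity(self):
        np.testing.assert_allclose(tp.circulant_covariance(4, 0.0).values, np.eye(4))

    def test_first_row_pattern(self):
        # correlation decays with the shorter arc around the circle
        row = tp.circulant_covariance(5, 0.5).values[0]
        np.testing.assert_allclose(row, [1, 0.5, 0.25, 0.25, 0.5])

    def test_positive_semidefinite(self):
        lam = np.linalg.eigvalsh(tp.circulant_covariance(6, 0.8).values)
        assert lam.min() >= -1e-12

    @pytest.mark.parametrize("n", [4, 7, 16])
    @pytest.mark.parametrize("alpha", [0.2, 0.6])
    def test_symmetric_circulant(self, n, alpha):
        C = tp.circulant_covariance(n, alpha).values
        np.testing.assert_allclose(C, C.T)
        for shift in range(1, n):
            np.testing.assert_allclose(C[0], np.roll(C[shift], -shift))

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_alpha_domain(self, bad):
        with pytest.raises(ValueError):
            tp.circulant_covariance(5, bad)

    def test_min_size(self):
        with pytest.raises(ValueError):
            tp.circulant_covariance(1, 0.5)


class TestCyclicSpectrum:
    def test_alpha_zero_flat_spectrum(self):
        np.testing.assert_allclose(tp.cyclic_eigenvalues(7, 0.0), np.ones(7))

    def test_matches_numerical_eigenvalues(self):
        lam = np.sort(tp.cyclic_eigenvalues(8, 0.6))
        num = np.sort(np.linalg.eigvalsh(tp.circulant_covariance(8, 0.6).values))
        np.testing.assert_allclose(lam, num, atol=1e-8)

    @pytest.mark.parametrize("n,alpha", [(5, 0.3), (12, 0.7), (9, 0.5)])
    def test_trace_conservation(self, n, alpha):
        assert np.sum(tp.cyclic_eigenvalues(n, alpha)) == pytest.approx(n)

    def test_first_eigenvector_constant(self):
        V = tp.cyclic_eigenvectors(9)
        np.testing.assert_allclose(V[:, 0], np.full(9, 1 / 3.0))

    def test_entry_closed_form(self):
        # n=4, i=1, s=1: sqrt(2/4) cos(pi/2 - pi/4) = 0.5
        assert tp.cyclic_eigenvectors(4)[1, 1] == pytest.approx(0.5)

    def test_columns_orthonormal(self):
        V = tp.cyclic_eigenvectors(16)
        np.testing.assert_allclose(V.T @ V, np.eye(16), atol=1e-10)

    @pytest.mark.parametrize("n", [4, 8, 64, 256])
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_eigenpair_residual(self, n, alpha):
        C = tp.circulant_covariance(n, alpha).values
        lam = tp.cyclic_eigenvalues(n, alpha)
        V = tp.cyclic_eigenvectors(n)
        resid = np.abs(C @ V - V * lam).max()
        assert resid <= 1e-8

    def test_template_reconstructs_covariance(self):
        spec = tp.cyclic_template(10, 0.4)
        np.testing.assert_allclose(
            spec.covariance(), tp.circulant_covariance(10, 0.4).values, atol=1e-6
        )

    def test_sorted_descending_and_deterministic(self):
        a = tp.cyclic_template(11, 0.6)
        b = tp.cyclic_template(11, 0.6)
        assert np.all(np.diff(a.eigenvalues) <= 1e-12)
        np.testing.assert_array_equal(a.eigenvectors, b.eigenvectors)


class TestKMS:
    def test_small_example(self):
        np.testing.assert_allclose(
            tp.kms_covariance(3, 0.5).values,
            [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]],
        )

    def test_alpha_zero_identity(self):
        np.testing.assert_allclose(tp.kms_covariance(4, 0.0).values, np.eye(4))

    def test_positive_definite(self):
        lam = np.linalg.eigvalsh(tp.kms_covariance(50, 0.9).values)
        assert lam.min() > 0

    def test_approx_eigenvalues_positive(self):
        assert tp.linear_eigenvalues(10, 0.5).min() > 0

    def test_approx_alpha_zero(self):
        np.testing.assert_allclose(tp.linear_eigenvalues(6, 0.0), np.ones(6))

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.7])
    def test_approx_within_5_percent(self, alpha):
        approx = np.sort(tp.linear_eigenvalues(100, alpha))
        exact = np.sort(np.linalg.eigvalsh(tp.kms_covariance(100, alpha).values))
        assert np.abs((approx - exact) / exact).max() <= 0.05

    def test_approx_error_decreases_with_n(self):
        errs = []
        for n in (10, 50, 200):
            approx = np.sort(tp.linear_eigenvalues(n, 0.7))
            exact = np.sort(np.linalg.eigvalsh(tp.kms_covariance(n, 0.7).values))
            errs.append(np.abs((approx - exact) / exact).max())
        assert errs[0] > errs[1] > errs[2]


class TestNumericalTemplate:
    def test_identity_reconstruction(self):
        spec = tp.numerical_template(tp.Covariance(np.eye(6)))
        np.testing.assert_allclose(spec.eigenvalues, np.ones(6))
        np.testing.assert_allclose(spec.covariance(), np.eye(6), atol=1e-10)

    def test_matches_analytic_circulant(self):
        spec = tp.numerical_template(tp.circulant_covariance(8, 0.6))
        np.testing.assert_allclose(
            np.sort(spec.eigenvalues), np.sort(tp.cyclic_eigenvalues(8, 0.6)), atol=1e-8
        )

    def test_drop_top_removes_constant_direction(self):
        spec = tp.cyclic_template(12, 0.5, drop_top=True)
        ones = np.ones(12)
        proj = spec.eigenvectors.T @ ones
        assert np.abs(proj).max() <= 1e-8
        assert spec.dropped_top and spec.m == 11

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            tp.numerical_template(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_rejects_indefinite(self):
        M = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="indefinite"):
            tp.numerical_template(M)

    def test_trace_conservation_kms(self):
        spec = tp.numerical_template(tp.kms_covariance(20, 0.6))
        assert spec.eigenvalues.sum() == pytest.approx(20)

    def test_save_load_roundtrip(self, tmp_path):
        spec = tp.cyclic_template(7, 0.3, drop_top=True)
        path = tmp_path / "spec.npz"
        spec.save(path)
        loaded = tp.TemplateSpectrum.load(path)
        assert loaded.kind == "cyclic" and loaded.dropped_top
        assert loaded.alpha == pytest.approx(0.3)
        np.testing.assert_allclose(loaded.eigenvectors, spec.eigenvectors)


class TestClusterTemplate:
    def test_single_cluster_full_corr(self):
        C = tp.cluster_covariance(["a", "a", "a"], within_corr=1.0)
        np.testing.assert_allclose(C.values, np.ones((3, 3)))

    def test_two_cluster_blocks(self):
        C = tp.cluster_covariance(["a", "a", "b"], within_corr=0.5)
        np.testing.assert_allclose(C.values, [[1, 0.5, 0], [0.5, 1, 0], [0, 0, 1]])

    def test_positive_semidefinite(self, rng):
        labels = rng.integers(0, 3, size=20)
        C = tp.cluster_covariance(labels, within_corr=0.9)
        assert np.linalg.eigvalsh(C.values).min() >= -1e-10
        assert C.values.trace() == pytest.approx(20)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            tp.cluster_covariance([], 0.5)


class TestBlockCirculant:
    def test_single_block_equals_circulant(self):
        C = tp.block_circulant_covariance([6], [0.5])
        np.testing.assert_allclose(C.values, tp.circulant_covariance(6, 0.5).values)

    def test_zero_cross_is_block_diagonal(self):
        C = tp.block_circulant_covariance([4, 4], [0.5, 0.5], cross_corr=0.0).values
        np.testing.assert_allclose(C[:4, :4], tp.circulant_covariance(4, 0.5).values)
        np.testing.assert_allclose(C[4:, :4], np.zeros((4, 4)))

    def test_small_cross_stays_psd(self):
        C = tp.block_circulant_covariance([8, 8], [0.6, 0.3], cross_corr=0.1)
        assert np.linalg.eigvalsh(C.values).min() >= -1e-8

    def test_large_cross_rejected(self):
        with pytest.raises(ValueError, match="cross_corr"):
            tp.block_circulant_covariance([4, 4], [0.9, 0.9], cross_corr=0.95)


class TestSpatialTemplate:
    def test_collinear_chain_distances_and_diag(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        spec = tp.spatial_affinity_template(coords, k_neighbors=1, bandwidth=1.0)
        # d(1,3)=2 along the symmetrized chain -> affinity exp(-4/2)
        aff = spec.covariance()
        assert aff[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert aff[0, 2] == pytest.approx(np.exp(-2.0), abs=1e-6)

    def test_symmetric_affinity_and_clipping(self, rng):
        coords = rng.random((30, 2))
        spec = tp.spatial_affinity_template(coords, k_neighbors=5)
        assert spec.eigenvalues.min() >= 0
        aff = spec.covariance()
        np.testing.assert_allclose(aff, aff.T, atol=1e-12)

    def test_disconnected_graph_reported(self):
        coords = np.array([[0, 0], [0.1, 0], [10, 10], [10.1, 10]], dtype=float)
        with pytest.raises(ValueError, match="2 components"):
            tp.spatial_affinity_template(coords, k_neighbors=1)
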