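"""Projector decomposition, dimension reduction, subspace similarity."""

import numpy as np
import pytest

from conndiff import (
    NoiseSpec,
    TimeSeriesData,
    analytic_covariance,
    critical_coupling,
    goodness_of_fit,
    make_windows,
    matrix_correlation,
    projector_set,
    reduced_covariance,
    simulate_ou,
    subspace_similarity,
    window_covariances,
    window_decomposition,
)
from conftest import random_symmetric_net, stable_coupling


class TestProjectorSet:
    def test_exchange_covariance_eigensystem(self, exchange_cov):
        dec = projector_set(exchange_cov)
        assert np.allclose(dec.eigenvalues, [1.0, 1.0 / 3.0])
        u0 = dec.eigenvectors[:, 0]
        u1 = dec.eigenvectors[:, 1]
        assert np.allclose(np.abs(u0), 1 / np.sqrt(2))
        assert np.allclose(np.abs(u1), 1 / np.sqrt(2))
        assert np.isclose(abs(u0 @ u1), 0.0, atol=1e-12)

    def test_projectors_sum_to_identity_and_reconstruct(self):
        C, _ = _fwd(7, seed=1)
        dec = projector_set(C)
        P = dec.projectors
        assert np.allclose(P.sum(axis=0), np.eye(7), atol=1e-12)
        assert np.max(np.abs(dec.reconstruct() - C)) < 1e-10
        # idempotent and mutually orthogonal rank-1 projectors
        for i in range(3):
            assert np.allclose(P[i] @ P[i], P[i], atol=1e-12)
            for j in range(i + 1, 3):
                assert np.allclose(P[i] @ P[j], 0.0, atol=1e-12)

    def test_identity_input_reconstructs_exactly(self):
        dec = projector_set(np.eye(4))
        assert np.allclose(dec.reconstruct(), np.eye(4))
        assert np.allclose(dec.projectors.sum(axis=0), np.eye(4))

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            projector_set(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_deterministic_sign_convention(self):
        C, _ = _fwd(6, seed=2)
        a = projector_set(C)
        b = projector_set(C)
        assert np.array_equal(a.eigenvectors, b.eigenvectors)
        idx = np.argmax(np.abs(a.eigenvectors), axis=0)
        assert np.all(a.eigenvectors[idx, np.arange(6)] > 0)


def _fwd(n, seed, frac=0.8):
    net = random_symmetric_net(n, seed=seed)
    c = stable_coupling(net, frac)
    return analytic_covariance(net, c, NoiseSpec(1.0)), (net, c)


class TestSharedEigenvectors:
    def test_structure_and_covariance_share_eigenbasis(self):
        """Model prediction: W and its stationary covariance have the same
        eigenvectors; covariance eigenvalues are -sigma^2/2 / (-1 + c lam)."""
        net = random_symmetric_net(9, seed=3)
        c = stable_coupling(net, 0.8)
        C = analytic_covariance(net, c, NoiseSpec(1.0))
        dec_w = projector_set(net.weights)
        dec_c = projector_set(C)
        sim = subspace_similarity(dec_w.eigenvectors, dec_c.eigenvectors)
        assert sim == pytest.approx(1.0, abs=1e-10)
        lam = np.sort(dec_w.eigenvalues)[::-1]
        pred = -0.5 / (-1.0 + c * lam)  # descending in lam -> descending in mu
        assert np.allclose(np.sort(pred)[::-1], dec_c.eigenvalues, rtol=1e-10)


class TestWindowDecomposition:
    def _ts(self, T=300, n=4, seed=4):
        rng = np.random.default_rng(seed)
        return TimeSeriesData(rng.normal(size=(T, n)) @ rng.normal(size=(n, n)), dt=1.0)

    def test_whole_series_window_diagonalizes(self):
        ts = self._ts()
        basis = projector_set(ts.covariance())
        spec = make_windows(ts, length_s=ts.n_samples * 1.0, step_s=1.0)
        dec = window_decomposition(ts, spec, basis)
        assert np.allclose(dec.projector_coeffs[0], basis.eigenvalues, atol=1e-10)
        assert np.max(np.abs(dec.mixed_coeffs[0])) < 1e-10

    def test_coefficients_match_basis_rotation_oracle(self):
        ts = self._ts(T=90, n=3)
        basis = projector_set(ts.covariance())
        spec = make_windows(ts, length_s=30.0, step_s=30.0)
        dec = window_decomposition(ts, spec, basis)
        covs = window_covariances(ts, spec)
        U = basis.eigenvectors
        for k in range(spec.n_windows):
            M = U.T @ covs[k] @ U  # brute-force rotation
            assert np.allclose(np.diag(M), dec.projector_coeffs[k], atol=1e-12)
            off = M - np.diag(np.diag(M))
            assert np.allclose(off, dec.mixed_coeffs[k], atol=1e-12)

    def test_full_reconstruction_is_exact(self):
        ts = self._ts(T=200, n=5, seed=5)
        basis = projector_set(ts.covariance())
        spec = make_windows(ts, length_s=60.0, step_s=40.0)
        dec = window_decomposition(ts, spec, basis)
        covs = window_covariances(ts, spec)
        full = reduced_covariance(dec, basis, k=5)
        assert np.max(np.abs(full - covs)) < 1e-10

    def test_mismatched_basis_rejected(self):
        ts = self._ts(n=4)
        basis = projector_set(np.eye(5))
        spec = make_windows(ts, length_s=50.0, step_s=50.0)
        with pytest.raises(ValueError, match="dimension"):
            window_decomposition(ts, spec, basis)


class TestReducedCovariance:
    def test_rank_one_signal_is_exact_at_k_one(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=4)
        X = rng.normal(size=(100, 1)) @ v[None, :]
        X += 1e-9 * rng.normal(size=X.shape)  # avoid exactly degenerate cov
        ts = TimeSeriesData(X, dt=1.0)
        basis = projector_set(ts.covariance())
        spec = make_windows(ts, length_s=50.0, step_s=50.0)
        dec = window_decomposition(ts, spec, basis)
        red = reduced_covariance(dec, basis, k=1)
        covs = window_covariances(ts, spec)
        assert np.max(np.abs(red - covs)) < 1e-6

    def test_top_terms_beat_complementary_terms(self):
        """On stationary OU data the top-3 projector/mixed reconstruction
        correlates better with the window covariance than the remainder."""
        net = random_symmetric_net(6, seed=7)
        c = stable_coupling(net, 0.8)
        ts = simulate_ou(net, c, duration=2000.0, dt=0.1, seed=8)
        basis = projector_set(ts.covariance())
        spec = make_windows(ts, length_s=200.0, step_s=200.0)
        dec = window_decomposition(ts, spec, basis)
        covs = window_covariances(ts, spec)
        top = reduced_covariance(dec, basis, k=3)
        rs_top, rs_rest = [], []
        for k in range(spec.n_windows):
            rest = covs[k] - top[k]
            rs_top.append(matrix_correlation(top[k], covs[k]))
            rs_rest.append(matrix_correlation(rest, covs[k]))
        assert np.mean(rs_top) > np.mean(rs_rest)

    def test_k_out_of_range_rejected(self):
        ts = TimeSeriesData(np.random.default_rng(0).normal(size=(50, 3)), dt=1.0)
        basis = projector_set(ts.covariance())
        spec = make_windows(ts, length_s=50.0, step_s=1.0)
        dec = window_decomposition(ts, spec, basis)
        with pytest.raises(ValueError):
            reduced_covariance(dec, basis, k=0)
        with pytest.raises(ValueError):
            reduced_covariance(dec, basis, k=4)


class TestGoodnessOfFit:
    def test_boundary_values(self):
        rng = np.random.default_rng(9)
        ts = TimeSeriesData(rng.normal(size=(80, 5)), dt=1.0)
        basis = projector_set(ts.covariance())
        assert goodness_of_fit(ts, basis, 0) == 0.0
        assert goodness_of_fit(ts, basis, 5) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(10)
        ts = TimeSeriesData(rng.normal(size=(100, 6)) @ rng.normal(size=(6, 6)), dt=1.0)
        basis = projector_set(ts.covariance())
        gofs = [goodness_of_fit(ts, basis, k) for k in range(7)]
        assert np.all(np.diff(gofs) >= -1e-12)

    def test_exact_for_series_in_low_dimensional_subspace(self):
        rng = np.random.default_rng(11)
        B = rng.normal(size=(2, 5))  # series confined to a 2-D subspace
        X = rng.normal(size=(120, 2)) @ B
        ts = TimeSeriesData(X, dt=1.0)
        basis = projector_set(ts.covariance())
        assert goodness_of_fit(ts, basis, 2) == pytest.approx(1.0, abs=1e-10)


class TestSubspaceSimilarity:
    def test_identical_and_orthogonal_subspaces(self):
        Q = np.linalg.qr(np.random.default_rng(12).normal(size=(6, 2)))[0]
        assert subspace_similarity(Q, Q) == pytest.approx(1.0)
        e1 = np.eye(4)[:, :1]
        e2 = np.eye(4)[:, 1:2]
        assert subspace_similarity(e1, e2) == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_cosine(self):
        a = np.array([[1.0], [0.0]])
        b = np.array([[0.5], [np.sqrt(3) / 2]])  # 60 degrees
        assert subspace_similarity(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_non_orthonormal_basis_rejected(self):
        bad = np.array([[1.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="orthonormal"):
            subspace_similarity(bad, bad)

    def test_aggregate_modes(self):
        rng = np.random.default_rng(13)
        Qa = np.linalg.qr(rng.normal(size=(8, 3)))[0]
        Qb = np.linalg.qr(rng.normal(size=(8, 3)))[0]
        mean_sim = subspace_similarity(Qa, Qb, aggregate="mean")
        first_sim = subspace_similarity(Qa, Qb, aggregate="first")
        assert 0.0 <= mean_sim <= first_sim <= 1.0
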