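"""Motion-dictionary estimation: moments, transitions, process covariances."""

import numpy as np
import pytest

import cinekalman as ck
from cinekalman.dictionary import (
    CardiacMotionDictionary,
    gaussian_denoiser,
    preprocess_training,
    process_cov_random_walk,
)

from conftest import random_series


def brute_force_cov(frames, l):
    """Direct double-loop evaluation of the lag-l pixel-pair covariances."""
    T, N = frames.shape[0], frames.shape[1]
    n = N * N
    B = frames.reshape(T, n).T
    mu = B.mean(axis=1)
    C = np.zeros((n, n), complex)
    for p in range(n):
        for q in range(n):
            C[p, q] = (
                sum(
                    (B[p, (t + l) % T] - mu[p]) * np.conj(B[q, t] - mu[q])
                    for t in range(T)
                )
                / T
            )
    return C


class TestTemporalMoments:
    def test_constant_series_zero_covariance(self):
        frames = np.full((4, 3, 3), 2.0 + 1.0j)
        d = CardiacMotionDictionary().fit(frames)
        assert np.allclose(d.means_, 2.0 + 1.0j)
        for l in range(4):
            assert np.allclose(d.cov_for_lag(l), 0.0, atol=1e-14)

    def test_single_pixel_two_frames_by_hand(self):
        # values {1, 3}: mean 2, c(0) = 1, c(1) = -1 (circular wrap)
        frames = np.array([1.0, 3.0]).reshape(2, 1, 1).astype(complex)
        d = CardiacMotionDictionary().fit(frames)
        assert d.means_[0] == pytest.approx(2.0)
        assert d.cov_for_lag(0)[0, 0] == pytest.approx(1.0)
        assert d.cov_for_lag(1)[0, 0] == pytest.approx(-1.0)

    def test_matches_brute_force_double_loop(self, rng):
        series = random_series(rng, T=6, N=4)
        d = CardiacMotionDictionary().fit(series)
        for l in [0, 1, 3, 5, -2, -4]:
            assert np.allclose(d.cov_for_lag(l), brute_force_cov(series.frames, l), atol=1e-12)

    def test_c0_hermitian_psd(self, rng):
        d = CardiacMotionDictionary().fit(random_series(rng, T=6, N=4))
        C0 = d.cov_for_lag(0)
        assert np.linalg.norm(C0 - C0.conj().T) <= 1e-10 * np.linalg.norm(C0)
        w = np.linalg.eigvalsh(C0)
        assert w.min() >= -1e-10 * w.max()

    def test_conjugate_symmetry_across_lags(self, rng):
        d = CardiacMotionDictionary().fit(random_series(rng, T=5, N=3))
        for l in range(1, 5):
            assert np.allclose(d.cov_for_lag(-l), d.cov_for_lag(l).conj().T, atol=1e-12)

    def test_lag_out_of_range_rejected(self, rng):
        d = CardiacMotionDictionary().fit(random_series(rng, T=4, N=2))
        with pytest.raises(ValueError):
            d.cov_for_lag(4)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            CardiacMotionDictionary().fit(np.ones((1, 3, 3), complex))


class TestTransitions:
    def test_first_step_is_identity_with_zero_bias(self, rng):
        d = CardiacMotionDictionary().fit(random_series(rng, T=4, N=3))
        tr = d.transition_for_lag(0, first_step=True)
        x = rng.standard_normal(9) + 1j * rng.standard_normal(9)
        assert np.array_equal(tr.apply(x), x)
        assert np.allclose(tr.matrix, np.eye(9))

    def test_disjoint_support_training_predicted_exactly_all_lags(self):
        # frames with pairwise-disjoint supports: rank T-1 centered matrix,
        # so every training frame maps exactly to its lag-shifted partner
        T, N = 5, 4
        frames = np.zeros((T, N, N), complex)
        for t in range(T):
            frames[t].flat[3 * t : 3 * t + 3] = [1.0 + 0.5j, 2.0, 0.5 - 1.0j]
        d = CardiacMotionDictionary().fit(frames)
        for l in range(-(T - 1), T):
            tr = d.transition_for_lag(l)
            for t in range(T):
                pred = tr.apply(frames[t].ravel())
                target = frames[(t + l) % T].ravel()
                assert np.linalg.norm(pred - target) <= 1e-8 * max(np.linalg.norm(target), 1)

    def test_lag_zero_is_identity_on_training_span(self, rng):
        series = random_series(rng, T=6, N=3)
        d = CardiacMotionDictionary().fit(series)
        tr = d.transition_for_lag(0)
        for t in range(6):
            x = series.frames[t].ravel()
            assert np.linalg.norm(tr.apply(x) - x) <= 1e-8 * np.linalg.norm(x)

    def test_mean_preservation_every_lag(self, rng):
        d = CardiacMotionDictionary().fit(random_series(rng, T=6, N=4))
        for l in range(-5, 6):
            tr = d.transition_for_lag(l)
            assert np.linalg.norm(tr.apply(d.means_) - d.means_) <= 1e-10 * np.linalg.norm(d.means_)

    def test_lmmse_matches_normal_equations_oracle(self, rng):
        # brute-force least-squares minimizer of sum_t ||y_{t+l} - F y_t||^2
        series = random_series(rng, T=8, N=4)
        d = CardiacMotionDictionary().fit(series)
        T, n = 8, 16
        B = series.frames.reshape(T, n).T
        Y = B - B.mean(axis=1, keepdims=True)
        for l in [1, 3, -2]:
            Yl = Y[:, (np.arange(T) + l) % T]
            F = np.linalg.lstsq(Y.T, Yl.T, rcond=None)[0].T  # min-norm solution
            assert np.linalg.norm(F - d.transition_for_lag(l).matrix) <= 1e-6 * np.linalg.norm(F)

    def test_factored_covariance_propagation_matches_dense(self, rng):
        d = CardiacMotionDictionary().fit(random_series(rng, T=5, N=3))
        tr = d.transition_for_lag(2)
        P = rng.standard_normal((9, 9)) + 1j * rng.standard_normal((9, 9))
        P = P @ P.conj().T
        f = tr.matrix
        assert np.allclose(tr.apply_cov(P), f @ P @ f.conj().T, rtol=1e-10)


class TestProcessCovariances:
    def test_two_stage_q_is_diagonal_of_c0(self, rng):
        series = random_series(rng, T=6, N=4)
        d = CardiacMotionDictionary().fit(series)
        Q = d.process_cov_two_stage()
        C0 = d.cov_for_lag(0)
        assert np.allclose(Q.diag, np.diag(C0).real, atol=1e-12)
        P = np.zeros((16, 16), complex)
        out = Q.add_to(P)
        assert np.allclose(out, np.diag(np.diag(C0).real), atol=1e-12)

    def test_two_stage_q_zero_for_constant_series(self):
        d = CardiacMotionDictionary().fit(np.full((4, 3, 3), 1.0 + 0j))
        assert np.allclose(d.process_cov_two_stage().diag, 0.0)

    def test_random_walk_q_zero_for_constant_and_ramp(self):
        frames = np.zeros((5, 2, 2), complex)
        frames[:, 0, 0] = 3.0  # constant pixel
        frames[:, 1, 1] = np.arange(5)  # linear ramp: constant differences
        series = ck.CineSeries(frames=frames, phase_labels=np.arange(1, 6), period_T=5)
        Q = process_cov_random_walk(series)
        assert Q.diag[0] == pytest.approx(0.0, abs=1e-14)
        assert Q.diag[3] == pytest.approx(0.0, abs=1e-14)

    def test_random_walk_q_matches_brute_force(self, rng):
        series = random_series(rng, T=6, N=3)
        Q = process_cov_random_walk(series)
        flat = series.frames.reshape(6, 9)
        for p in range(9):
            diffs = np.diff(flat[:, p])
            expected = np.var(diffs)  # variance of the difference images
            assert Q.diag[p] == pytest.approx(expected, rel=1e-10)


class TestPreprocessing:
    def test_default_hook_is_identity(self, rng):
        series = random_series(rng, T=4, N=4)
        out = preprocess_training(series, None)
        assert np.array_equal(out.frames, series.frames)

    def test_gaussian_hook_reduces_noise_variance(self, rng):
        noise = rng.standard_normal((3, 16, 16)) + 1j * rng.standard_normal((3, 16, 16))
        series = ck.CineSeries(frames=noise, phase_labels=np.arange(1, 4), period_T=3)
        out = preprocess_training(series, gaussian_denoiser(1.0))
        assert np.var(out.frames.real) < np.var(series.frames.real)

    def test_shape_changing_hook_rejected(self, rng):
        series = random_series(rng, T=3, N=4)
        with pytest.raises(ValueError):
            preprocess_training(series, lambda f: f[:2, :2])

    def test_grid_cap_enforced(self):
        big = np.zeros((2, 128, 128), complex)
        with pytest.raises(ValueError, match="cap"):
            CardiacMotionDictionary().fit(big)
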