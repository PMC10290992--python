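"""Kalman filtering: lag schedules, initialization, predict/update contracts."""

import numpy as np
import pytest

import cinekalman as ck
from cinekalman.dictionary import CardiacMotionDictionary, ProcessCov
from cinekalman.kalman import (
    FilterConfig,
    KalmanReconstructor,
    KalmanState,
    estimate_background_sigma2,
    init_filter,
    interp_step_params,
    lag_schedule,
    predict_step,
    run_reconstruction,
    update_step,
)

from conftest import random_series


class TestLagSchedule:
    def test_wrap_from_phase_50_to_1(self):
        labels = list(range(1, 51)) + [1]
        lags = lag_schedule(labels, 50)
        assert lags[-1] == -49

    def test_early_return_from_phase_30(self):
        assert lag_schedule([30, 1], 50) == [None, -29]

    def test_skip_every_other_phase(self):
        assert lag_schedule([1, 3, 5], 50) == [None, 2, 2]

    def test_first_frame_flagged(self):
        assert lag_schedule([7], 50) == [None]

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            lag_schedule([1, 51], 50)

    def test_empty_schedule(self):
        assert lag_schedule([], 50) == []


class TestInterpStepParams:
    def test_block_walk_is_consistent(self):
        # V=5, T_train=4: steps into phases 2..6 use v = 5..1 anchored at 1
        got = [interp_step_params(q, 5, 4) for q in [2, 3, 4, 5, 6]]
        assert [v for _, v in got] == [5, 4, 3, 2, 1]
        assert all(l == 1 for l, _ in got)
        # wrap block (anchor at training phase 4, end at phase 1 of next beat)
        got = [interp_step_params(q, 5, 4) for q in [17, 18, 19, 20, 1]]
        assert [v for _, v in got] == [5, 4, 3, 2, 1]
        assert all(l == 1 - 4 for l, _ in got)


class TestInitFilter:
    def test_user_supplied_zero_noise(self, small_pair):
        train, _ = small_pair
        state, r = init_filter(train, None, FilterConfig(R_sigma2=0.0, P0_sigma2=0.5))
        assert r == 0.0
        assert np.array_equal(state.x_a, train.frames[0].ravel())
        assert np.allclose(np.diag(state.P_a), 0.5)

    def test_noiseless_constant_background_estimates_zero(self, small_pair):
        train, _ = small_pair
        img = train.frames[0].copy()
        img[:4, :4] = 0.7 + 0.2j  # constant patch
        var = estimate_background_sigma2(img, (slice(0, 4), slice(0, 4)))
        assert var <= 1e-12

    def test_roi_noise_estimate_within_ten_percent(self):
        # 16x16 ROI of complex white noise, averaged over 100 seeds
        sigma2 = 0.04
        ests = []
        for seed in range(100):
            g = np.random.default_rng(seed)
            noise = np.sqrt(sigma2 / 2) * (
                g.standard_normal((16, 16)) + 1j * g.standard_normal((16, 16))
            )
            ests.append(estimate_background_sigma2(noise, (slice(None), slice(None))))
        assert np.mean(ests) == pytest.approx(sigma2, rel=0.10)

    def test_empty_roi_rejected(self, small_pair):
        train, _ = small_pair
        with pytest.raises(ValueError):
            estimate_background_sigma2(train.frames[0], (slice(0, 0), slice(0, 0)))


class TestPredictStep:
    def test_identity_transition_zero_q_leaves_state(self, rng):
        n = 9
        d = CardiacMotionDictionary().fit(random_series(rng, T=4, N=3))
        tr = d.transition_for_lag(0, first_step=True)
        P = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        P = P @ P.conj().T
        x = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        out = predict_step(KalmanState(x_a=x, P_a=P), tr, None)
        assert np.array_equal(out.x_a, x)
        assert np.allclose(out.P_a, P)

    def test_exact_dictionary_predicts_true_next_frame(self):
        # disjoint-support training: stage one alone reproduces the next frame
        T, N = 4, 3
        frames = np.zeros((T, N, N), complex)
        for t in range(T):
            frames[t].flat[2 * t : 2 * t + 2] = [1.0, 0.5 + 0.5j]
        d = CardiacMotionDictionary().fit(frames)
        tr = d.transition_for_lag(1)
        state = KalmanState(x_a=frames[1].ravel(), P_a=np.zeros((9, 9), complex))
        out = predict_step(state, tr, None)
        assert np.linalg.norm(out.x_a - frames[2].ravel()) <= 1e-6


class TestUpdateStep:
    def test_gain_definition_identity(self, rng):
        # K S = P G^H for the computed gain (S invertible with R > 0)
        N = 4
        pat = ck.cartesian_mask(N, 2, seed=0)
        op = ck.build_operator(pat)
        n, m = N * N, op.n_samples
        P = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        P = P @ P.conj().T
        R = 1e-3
        GP = op.apply_to_matrix(P)
        PGH = GP.conj().T
        S = op.apply_to_matrix(PGH)
        S[np.diag_indices_from(S)] += R
        K = PGH @ np.linalg.pinv(S, hermitian=True)
        assert np.linalg.norm(K @ S - PGH) <= 1e-8 * np.linalg.norm(PGH)

    def test_full_sampling_low_noise_recovers_inverse_dft(self, rng):
        N = 8
        op = ck.build_operator(ck.cartesian_mask(N, N, seed=0))
        truth = rng.standard_normal((N, N)) + 1j * rng.standard_normal((N, N))
        z = op.forward(truth)
        n = N * N
        state = KalmanState(x_a=np.zeros(n, complex), P_a=np.eye(n, dtype=complex))
        kf = ck.KSpaceFrame(samples=z, pattern=op.pattern)
        out = update_step(state, kf, op, R_sigma2=1e-12)
        assert np.linalg.norm(out.x_a - truth.ravel()) <= 1e-6 * np.linalg.norm(truth)

    def test_infinite_noise_returns_prediction(self, rng):
        N = 8
        op = ck.build_operator(ck.radial_trajectory(N, 2))
        x_f = rng.standard_normal(N * N) + 1j * rng.standard_normal(N * N)
        state = KalmanState(x_a=x_f.copy(), P_a=np.eye(N * N, dtype=complex))
        z = rng.standard_normal(op.n_samples) + 1j * rng.standard_normal(op.n_samples)
        kf = ck.KSpaceFrame(samples=z, pattern=op.pattern)
        out = update_step(state, kf, op, R_sigma2=1e12)
        assert np.linalg.norm(out.x_a - x_f) <= 1e-9 * np.linalg.norm(x_f)

    def test_update_never_worsens_sampled_data_fit(self, small_pair):
        # ||G x_a - z|| <= ||G x_f - z|| at every step (noisy data, small R)
        train, test = small_pair
        truth, sched = ck.build_scenario(train, test, ck.ScenarioSpec(kind="periodic", n_cycles=1))
        pats = [ck.radial_trajectory(16, 2, frame_index=i) for i in range(truth.n_frames)]
        kframes = ck.measure_series(truth, pats, noise_sigma=0.005, seed=3)
        d = CardiacMotionDictionary().fit(train)
        Q = d.process_cov_two_stage()
        state, _ = init_filter(train, None, FilterConfig(R_sigma2=1e-6, P0_sigma2=1e-2))
        lags = ck.lag_schedule(sched, train.period_T)
        for kf, lag in zip(kframes, lags):
            op = ck.build_operator(kf.pattern)
            tr = d.transition_for_lag(lag) if lag is not None else d.transition_for_lag(0, first_step=True)
            pred = predict_step(state, tr, Q)
            state = update_step(pred, kf, op, R_sigma2=1e-6)
            fit_before = np.linalg.norm(op.forward(pred.x_a.reshape(16, 16)) - kf.samples)
            fit_after = np.linalg.norm(op.forward(state.x_a.reshape(16, 16)) - kf.samples)
            assert fit_after <= fit_before * (1 + 1e-10)

    def test_covariance_stays_hermitian_psd(self, small_pair):
        train, test = small_pair
        truth, sched = ck.build_scenario(train, test, ck.ScenarioSpec(kind="periodic", n_cycles=1))
        pats = [ck.radial_trajectory(16, 2, frame_index=i) for i in range(truth.n_frames)]
        kframes = ck.measure_series(truth, pats, noise_sigma=0.01, seed=3)
        d = CardiacMotionDictionary().fit(train)
        Q = d.process_cov_two_stage()
        state, _ = init_filter(train, None, FilterConfig(R_sigma2=1e-4, P0_sigma2=1e-2))
        lags = ck.lag_schedule(sched, train.period_T)
        for kf, lag in zip(kframes, lags):
            op = ck.build_operator(kf.pattern)
            tr = d.transition_for_lag(lag) if lag is not None else d.transition_for_lag(0, first_step=True)
            state = update_step(predict_step(state, tr, Q), kf, op, R_sigma2=1e-4)
            P = state.P_a
            assert np.linalg.norm(P - P.conj().T) <= 1e-8 * max(np.linalg.norm(P), 1e-30)
            diag = np.diag(P)
            assert np.all(diag.real >= -1e-10 * max(diag.real.max(), 1e-30))
            w = np.linalg.eigvalsh(P)
            assert w.min() >= -1e-8 * max(w.max(), 1e-30)


class TestScalarOracle:
    def test_full_pipeline_matches_hand_coded_scalar_filter(self):
        # N = 1: the whole machinery must reduce to the textbook scalar filter
        rng = np.random.default_rng(0)
        T = 4
        train_vals = np.array([1.0, 2.0, 1.5, 0.5]) + 1j * np.array([0.2, -0.1, 0.3, 0.0])
        train = ck.CineSeries(
            frames=train_vals.reshape(T, 1, 1),
            phase_labels=np.arange(1, T + 1),
            period_T=T,
            is_training=True,
        )
        n_steps = 100
        labels = [(t % T) + 1 for t in range(n_steps)]
        truth_vals = train_vals[np.array(labels) - 1] + 0.05 * (
            rng.standard_normal(n_steps) + 1j * rng.standard_normal(n_steps)
        )
        pat = ck.cartesian_mask(1, 1, seed=0)
        op = ck.build_operator(pat)
        sigma = 0.03
        noise = sigma / np.sqrt(2) * (rng.standard_normal(n_steps) + 1j * rng.standard_normal(n_steps))
        kframes = [
            ck.KSpaceFrame(samples=np.array([truth_vals[t] + noise[t]]), pattern=pat)
            for t in range(n_steps)
        ]
        R, P0 = sigma**2, 0.1
        res = run_reconstruction(
            train, kframes, labels, FilterConfig(R_sigma2=R, P0_sigma2=P0)
        )
        got = res.frames.frames[:, 0, 0]

        # hand-coded scalar Kalman recursion with the same statistics
        mu = train_vals.mean()
        y = train_vals - mu
        c = {l: np.mean(y[(np.arange(T) + l) % T] * np.conj(y)) for l in range(-(T - 1), T)}
        q = c[0].real
        x, p = train_vals[0], P0
        expect = np.empty(n_steps, complex)
        prev = None
        for t in range(n_steps):
            if prev is None:
                f, b = 1.0, 0.0
            else:
                l = labels[t] - prev
                f = c[l] / c[0]
                b = mu - f * mu
            x_f = f * x + b
            p_f = abs(f) ** 2 * p + q
            z = kframes[t].samples[0]
            K = p_f / (p_f + R)
            x = x_f + K * (z - x_f)
            p = (1 - K) * p_f
            expect[t] = x
            prev = labels[t]
        assert np.allclose(got, expect, rtol=1e-10, atol=1e-12)


class TestRunReconstruction:
    def test_zero_frames_empty_result(self, small_pair):
        train, _ = small_pair
        model = KalmanReconstructor(R_sigma2=1e-4, P0_sigma2=1e-2).fit(train)
        res = model.predict([], [])
        assert res.frames.n_frames == 0
        assert res.mse_trace.size == 0

    def test_mismatched_labels_rejected(self, small_pair):
        train, _ = small_pair
        pat = ck.cartesian_mask(16, 4, seed=0)
        kfr = ck.measure_series(train, pat, seed=0)
        model = KalmanReconstructor(R_sigma2=1e-4, P0_sigma2=1e-2).fit(train)
        with pytest.raises(ValueError):
            model.predict(kfr, [1, 2])

    def test_estimator_params_roundtrip(self):
        model = KalmanReconstructor(variant="random_walk", temporal_factor=2)
        params = model.get_params()
        clone = KalmanReconstructor(**params)
        assert clone.get_params() == params
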