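"""Two-stage and random-walk Kalman filtering over undersampled k-space.

The filter alternates a prediction step driven by the learned motion
dictionary (stage one) with a measurement update against acquired k-space
(stage two):

    x_t^f = f_t x_{t-1}^a + b_t             P_t^f = f_t P_{t-1}^a f_t^H + Q
    K_t   = P_t^f G^H (G P_t^f G^H + R)^+   with G = E F
    x_t^a = x_t^f + K_t (z_t - G x_t^f)     P_t^a = (I - K_t G) P_t^f

The innovation covariance is formed in the m-dimensional sample space
(m = samples per frame), so the pseudoinverse is an m x m operation.  The
Jacobian of the affine stage-one model is exactly ``f_t``; no numerical
differentiation exists anywhere.  ``P`` is re-Hermitianized each step to
control floating-point drift.

The random-walk baseline keeps the same update but uses an identity
transition and the difference-image ``Q``; a third variant (identity
transition with the *full* non-diagonal ``C_0`` as ``Q``) exposes the
divergence that motivates the predictive model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .dictionary import (
    CardiacMotionDictionary,
    ProcessCov,
    TransitionModel,
    _check_grid_cap,
    process_cov_random_walk,
)
from .interp import step_transition
from .sampling import KSpaceFrame, MeasurementOperator, build_operator
from .series import CineSeries

__all__ = [
    "KalmanState",
    "FilterConfig",
    "ReconResult",
    "lag_schedule",
    "interp_step_params",
    "estimate_background_sigma2",
    "init_filter",
    "predict_step",
    "update_step",
    "KalmanReconstructor",
    "run_reconstruction",
]


@dataclass
class KalmanState:
    """Current estimate and spatiotemporal covariance of the filter."""

    x_a: np.ndarray
    P_a: np.ndarray
    t: int = 0
    phase: int = 1


@dataclass
class FilterConfig:
    """Tunables of the reconstruction filter.

    ``R_sigma2`` / ``P0_sigma2`` may be given directly; when None they are
    estimated from a background region of interest (``background_roi``, a
    ``(row_slice, col_slice)`` pair) of a reference image.  ``temporal_factor``
    V > 1 activates the interpolated per-step transitions.
    """

    variant: str = "two_stage"
    R_sigma2: Optional[float] = None
    P0_sigma2: Optional[float] = None
    background_roi: Optional[tuple] = None
    temporal_factor: int = 1
    pinv_tol: float = 1e-10

    _VARIANTS = ("two_stage", "random_walk", "identity_full_cov")

    def __post_init__(self) -> None:
        if self.variant not in self._VARIANTS:
            raise ValueError(f"variant must be one of {self._VARIANTS}")
        if self.R_sigma2 is not None and self.R_sigma2 < 0:
            raise ValueError("R_sigma2 must be >= 0")
        if self.P0_sigma2 is not None and self.P0_sigma2 < 0:
            raise ValueError("P0_sigma2 must be >= 0")
        if self.temporal_factor < 1:
            raise ValueError("temporal_factor must be >= 1")


@dataclass
class ReconResult:
    """Reconstruction output: frames plus per-frame diagnostics."""

    frames: CineSeries
    mse_trace: Optional[np.ndarray] = None
    lag_trace: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def lag_schedule(phase_labels: Sequence[int], T: int) -> list:
    """Signed dictionary lag for every frame of a phase-label schedule.

    ``l_t = phase_t - phase_{t-1}``; the first frame is flagged ``None``
    (identity/first-step transition).  A wrap from phase T to phase 1 of the
    next beat gives ``l = -(T-1)``; an early return from phase p to phase 1
    gives ``l = -(p-1)``; retaining every other phase gives ``l = 2``.
    """
    labels = np.asarray(phase_labels, dtype=int)
    if labels.size == 0:
        return []
    if np.any(labels < 1) or np.any(labels > T):
        raise ValueError("phase labels must lie in [1, T]")
    lags: list = [None]
    for prev, cur in zip(labels[:-1], labels[1:]):
        l = int(cur) - int(prev)
        if abs(l) >= T:
            raise ValueError(f"|lag| must be < T, got {l}")
        lags.append(l)
    return lags


def interp_step_params(phase: int, V: int, T_train: int) -> tuple[int, int]:
    """Map a full-resolution phase to its (base_lag, v) per-step parameters.

    Training phases occupy test phases ``1, 1+V, 1+2V, ...``.  A step *into*
    test phase ``q`` lies in the block whose end is the next training phase at
    or above ``q``; ``v`` counts down from V (first step after the anchor) to
    1 (arrival at the block end).  The base lag is +1 inside the cycle and
    ``1 - T_train`` for the block that wraps to the next beat.
    """
    T_test = V * T_train
    q = phase
    if q == 1:
        return (1 - T_train if T_train > 1 else 0), 1
    rem = (q - 1) % V
    v = 1 if rem == 0 else V - rem + 1
    end_test_phase = ((q - 2) // V + 1) * V + 1
    end_train_idx = (end_test_phase - 1) // V + 1
    if end_train_idx > T_train:
        base_lag = 1 - T_train
    else:
        base_lag = 1
    return base_lag, v


def estimate_background_sigma2(image: np.ndarray, roi: Optional[tuple] = None) -> float:
    """Spatial variance of a background region of an image.

    With the orthonormal DFT convention, white noise has identical variance in
    image space and k-space, so this one number serves both R and P0.  The
    default ROI is the top-left corner quarter of the grid (air in the
    phantom geometry).
    """
    N = image.shape[0]
    if roi is None:
        roi = (slice(0, max(2, N // 4)), slice(0, max(2, N // 4)))
    patch = image[roi]
    if patch.size == 0:
        raise ValueError("background ROI is empty")
    return float(np.var(patch.real) + np.var(patch.imag))


def init_filter(
    train: CineSeries,
    sample_image: Optional[np.ndarray],
    config: FilterConfig,
) -> tuple[KalmanState, float]:
    """Initialize ``x_0^a``, ``P_0^a`` and the measurement-noise variance.

    ``x_0^a`` is the first training image (any image can seed the filter);
    ``P_0^a`` is diagonal with the background spatial variance; R = sigma^2 I
    with sigma^2 from the same background unless supplied directly.
    """
    N = train.grid_size
    _check_grid_cap(N)
    n = N * N
    if config.R_sigma2 is not None:
        r_sigma2 = float(config.R_sigma2)
    else:
        if sample_image is None:
            raise ValueError("R_sigma2 not given and no sample image to estimate it from")
        r_sigma2 = estimate_background_sigma2(sample_image, config.background_roi)
    if config.P0_sigma2 is not None:
        p0 = float(config.P0_sigma2)
    else:
        if sample_image is None:
            raise ValueError("P0_sigma2 not given and no sample image to estimate it from")
        p0 = estimate_background_sigma2(sample_image, config.background_roi)
    x0 = train.frames[0].reshape(n).astype(np.complex128)
    P0 = np.zeros((n, n), dtype=np.complex128)
    P0[np.diag_indices(n)] = p0
    return KalmanState(x_a=x0, P_a=P0, t=0, phase=int(train.phase_labels[0])), r_sigma2


def predict_step(state: KalmanState, transition, Q: Optional[ProcessCov]) -> KalmanState:
    """Stage one: propagate the estimate and covariance through the transition."""
    x_f = transition.apply(state.x_a)
    P_f = transition.apply_cov(state.P_a)
    if Q is not None:
        P_f = Q.add_to(P_f)
    return KalmanState(x_a=x_f, P_a=P_f, t=state.t, phase=state.phase)


def update_step(
    state_pred: KalmanState,
    kframe: KSpaceFrame,
    op: MeasurementOperator,
    R_sigma2: float,
    pinv_tol: float = 1e-10,
) -> KalmanState:
    """Stage two: blend the prediction with acquired k-space via the Kalman gain.

    The innovation covariance ``S = G P^f G^H + R`` is an explicit m x m
    matrix; the gain is applied through its (Hermitian) pseudoinverse.
    """
    x_f, P_f = state_pred.x_a, state_pred.P_a
    z = kframe.samples
    if z.shape[0] != op.n_samples:
        raise ValueError("sample vector inconsistent with operator")
    GP = op.apply_to_matrix(P_f)  # (m, n) = G P
    PGH = GP.conj().T  # P G^H since P is Hermitian
    S = op.apply_to_matrix(PGH)  # (m, m) = G P G^H
    S[np.diag_indices_from(S)] += R_sigma2
    S = 0.5 * (S + S.conj().T)
    S_pinv = np.linalg.pinv(S, rcond=pinv_tol, hermitian=True)
    K = PGH @ S_pinv
    innovation = z - op.forward(x_f.reshape(op.N, op.N))
    x_a = x_f + K @ innovation
    P_a = P_f - K @ GP
    P_a = 0.5 * (P_a + P_a.conj().T)
    return KalmanState(x_a=x_a, P_a=P_a, t=state_pred.t, phase=state_pred.phase)


class KalmanReconstructor(BaseEstimator):
    """Sequential reconstruction of undersampled cine frames.

    ``fit`` learns the motion dictionary (and/or process covariance) from one
    fully sampled training cycle; ``predict`` filters a sequence of k-space
    frames into images.

    Parameters mirror :class:`FilterConfig`; ``variant`` selects
    ``"two_stage"`` (predictive signal model), ``"random_walk"`` (identity
    transition, difference-image Q), or ``"identity_full_cov"`` (identity
    transition with full C_0 as Q — the divergence ablation).
    """

    def __init__(
        self,
        variant: str = "two_stage",
        R_sigma2: Optional[float] = None,
        P0_sigma2: Optional[float] = None,
        background_roi: Optional[tuple] = None,
        temporal_factor: int = 1,
        pinv_tol: float = 1e-10,
        denoiser=None,
    ):
        self.variant = variant
        self.R_sigma2 = R_sigma2
        self.P0_sigma2 = P0_sigma2
        self.background_roi = background_roi
        self.temporal_factor = temporal_factor
        self.pinv_tol = pinv_tol
        self.denoiser = denoiser

    def _config(self) -> FilterConfig:
        return FilterConfig(
            variant=self.variant,
            R_sigma2=self.R_sigma2,
            P0_sigma2=self.P0_sigma2,
            background_roi=self.background_roi,
            temporal_factor=self.temporal_factor,
            pinv_tol=self.pinv_tol,
        )

    def fit(self, X: CineSeries, y=None) -> "KalmanReconstructor":
        config = self._config()  # validates parameters early
        if not isinstance(X, CineSeries):
            X = CineSeries(
                frames=np.asarray(X, dtype=np.complex128),
                phase_labels=np.arange(1, np.asarray(X).shape[0] + 1),
                period_T=np.asarray(X).shape[0],
                is_training=True,
            )
        self.train_ = X
        self.dictionary_ = CardiacMotionDictionary(
            pinv_tol=self.pinv_tol, denoiser=self.denoiser
        ).fit(X)
        if config.variant == "two_stage":
            self.Q_ = self.dictionary_.process_cov_two_stage()
        elif config.variant == "random_walk":
            self.Q_ = process_cov_random_walk(X)
        else:  # identity_full_cov ablation
            self.Q_ = self.dictionary_.process_cov_full()
        return self

    # -- transition lookup -------------------------------------------------

    def _transition(self, lag, cache: dict):
        """Transition for one step: identity variants, plain lag, or (V, v) step."""
        if self.variant in ("random_walk", "identity_full_cov"):
            key = "identity"
            if key not in cache:
                cache[key] = self.dictionary_.transition_for_lag(0, first_step=True)
            return cache[key]
        if lag is None:
            key = "first"
            if key not in cache:
                cache[key] = self.dictionary_.transition_for_lag(0, first_step=True)
            return cache[key]
        if isinstance(lag, tuple):  # (base_lag, v) from the interp schedule
            base_lag, v = lag
            if lag not in cache:
                fV = self.dictionary_.transition_for_lag(base_lag)
                cache[lag] = step_transition(
                    fV, self.temporal_factor, v, pinv_tol=self.pinv_tol
                )
            return cache[lag]
        if lag not in cache:
            cache[lag] = self.dictionary_.transition_for_lag(lag)
        return cache[lag]

    def _schedule(self, phase_labels: np.ndarray):
        """Per-frame transition keys: lags at V=1, (base_lag, v) tuples at V>1."""
        V = self.temporal_factor
        T_train = self.dictionary_.T_
        if V == 1:
            return lag_schedule(phase_labels, T_train)
        T_test = V * T_train
        labels = np.asarray(phase_labels, dtype=int)
        if np.any(labels < 1) or np.any(labels > T_test):
            raise ValueError("phase labels must lie in [1, V * T_train]")
        steps = (np.diff(labels) - 1) % T_test
        if np.any(steps != 0):
            raise NotImplementedError(
                "temporal_factor > 1 supports sequential (+1, periodic) schedules"
            )
        keys: list = [None]
        for q in labels[1:]:
            keys.append(interp_step_params(int(q), V, T_train))
        return keys

    # -- main loop ---------------------------------------------------------

    def predict(
        self,
        kframes: Sequence[KSpaceFrame],
        phase_labels: Sequence[int],
        truth: Optional[CineSeries] = None,
    ) -> ReconResult:
        """Filter a k-space frame sequence into reconstructed images."""
        if len(kframes) != len(phase_labels):
            raise ValueError("need one phase label per k-space frame")
        N = self.train_.grid_size
        n = N * N
        labels = np.asarray(phase_labels, dtype=int)
        if len(kframes) == 0:
            empty = CineSeries(
                frames=np.zeros((1, N, N), np.complex128),
                phase_labels=np.array([1]),
                period_T=max(self.train_.period_T, 1),
            )
            empty.frames = empty.frames[:0]
            empty.phase_labels = empty.phase_labels[:0]
            return ReconResult(frames=empty, mse_trace=np.zeros(0), lag_trace=[])

        config = self._config()
        first_image = build_operator(kframes[0].pattern).adjoint(kframes[0].samples)
        state, r_sigma2 = init_filter(self.train_, first_image, config)

        keys = self._schedule(labels)
        cache: dict = {}
        recon = np.empty((len(kframes), N, N), dtype=np.complex128)
        mse = np.empty(len(kframes)) if truth is not None else None
        for i, (kf, key) in enumerate(zip(kframes, keys)):
            op = build_operator(kf.pattern)
            transition = self._transition(key, cache)
            state = predict_step(state, transition, self.Q_)
            state = update_step(state, kf, op, r_sigma2, pinv_tol=self.pinv_tol)
            state.t = i + 1
            state.phase = int(labels[i])
            recon[i] = state.x_a.reshape(N, N)
            if truth is not None:
                diff = recon[i] - truth.frames[i]
                mse[i] = float(np.mean(np.abs(diff) ** 2))
        frames = CineSeries(
            frames=recon,
            phase_labels=labels,
            period_T=self.train_.period_T * self.temporal_factor,
        )
        diagnostics = {"R_sigma2": r_sigma2, "variant": self.variant}
        return ReconResult(frames=frames, mse_trace=mse, lag_trace=keys, diagnostics=diagnostics)


def run_reconstruction(
    train: CineSeries,
    kframes: Sequence[KSpaceFrame],
    phase_labels: Sequence[int],
    config: FilterConfig,
    truth: Optional[CineSeries] = None,
) -> ReconResult:
    """Functional wrapper: fit a :class:`KalmanReconstructor` and filter."""
    model = KalmanReconstructor(
        variant=config.variant,
        R_sigma2=config.R_sigma2,
        P0_sigma2=config.P0_sigma2,
        background_roi=config.background_roi,
        temporal_factor=config.temporal_factor,
        pinv_tol=config.pinv_tol,
    )
    model.fit(train)
    return model.predict(kframes, phase_labels, truth=truth)
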