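"""Learned cardiac motion dictionary: temporal second-order statistics and
LMMSE phase transitions estimated from one fully sampled cardiac cycle.

Every pixel of the training cine is modeled as a temporally wide-sense
stationary (WSS) complex random process, jointly WSS across pixels.  From a
single cycle of ``T`` frames the dictionary estimates, with the biased ``1/T``
normalization and *circular* time indexing (lag wraps mod T):

- the temporal mean ``mu`` of every pixel,
- the lag-``l`` covariance matrices ``C_l`` between all pixel pairs
  (``C_{-l} = C_l^H`` by joint stationarity),
- the affine LMMSE transition for a signed phase lag ``l``:
  ``f = C_l pinv(C_0)``, ``b = mu - f mu``,
- two process-covariance variants: ``Q = diag(C_0)`` (two-stage) and the
  per-pixel variance of successive difference images (random-walk baseline).

``C_0`` has rank at most ``T - 1`` (it is an outer product of ``T`` centered
frames), so the Moore-Penrose pseudoinverse with a relative singular-value
cutoff is structural, not cosmetic.  Internally everything is kept in the
rank-``r`` factored form ``f = L @ Rh``; dense matrices are materialized on
demand.  Vectorization is row-major: pixel order (1,1), (1,2), ..., (N,N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator

from .series import CineSeries

__all__ = [
    "MAX_GRID_SIZE",
    "TransitionModel",
    "ProcessCov",
    "CardiacMotionDictionary",
    "preprocess_training",
    "gaussian_denoiser",
    "process_cov_random_walk",
]

#: hard cap on the grid size for dense N^2 x N^2 operations (f occupies N^4
#: complex entries; N=64 is ~256 MB and is the supported desk-scale maximum)
MAX_GRID_SIZE = 64


def _check_grid_cap(N: int) -> None:
    if N > MAX_GRID_SIZE:
        raise ValueError(
            f"grid size {N} exceeds the supported cap of {MAX_GRID_SIZE}; "
            "dense spatiotemporal covariances scale as N^4"
        )


@dataclass
class TransitionModel:
    """Affine phase transition ``x -> f x + b`` for a signed lag.

    ``f`` is stored either as the identity (first-step request) or in the
    factored form ``f = left @ right`` with rank <= T.  ``matrix`` densifies.
    """

    b: np.ndarray
    lag: int
    left: Optional[np.ndarray] = None  # (n, r)
    right: Optional[np.ndarray] = None  # (r, n)
    is_identity: bool = False

    @property
    def n(self) -> int:
        return self.b.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        if self.is_identity:
            return np.eye(self.n, dtype=np.complex128)
        return self.left @ self.right

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Predict: ``f x + b``."""
        if self.is_identity:
            return x + self.b
        return self.left @ (self.right @ x) + self.b

    def apply_cov(self, P: np.ndarray) -> np.ndarray:
        """Propagate a covariance: ``f P f^H`` (Jacobian of the affine map is f)."""
        if self.is_identity:
            return P.copy()
        RP = self.right @ P
        M = RP @ self.right.conj().T
        return self.left @ M @ self.left.conj().T


@dataclass
class ProcessCov:
    """Diagonal (or full) process covariance Q with real nonnegative diagonal."""

    diag: np.ndarray
    variant: str
    full: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.diag = np.asarray(self.diag, dtype=np.float64)
        if np.any(self.diag < -1e-12):
            raise ValueError("process covariance diagonal must be nonnegative")
        self.diag = np.maximum(self.diag, 0.0)

    def add_to(self, P: np.ndarray) -> np.ndarray:
        """Return ``P + Q`` (in place on P)."""
        if self.full is not None:
            P += self.full
        else:
            P[np.diag_indices_from(P)] += self.diag
        return P


def gaussian_denoiser(sigma: float = 0.7) -> Callable[[np.ndarray], np.ndarray]:
    """Small-sigma Gaussian smoothing hook applied to real and imaginary parts."""

    def denoise(frame: np.ndarray) -> np.ndarray:
        return gaussian_filter(frame.real, sigma) + 1j * gaussian_filter(frame.imag, sigma)

    return denoise


def preprocess_training(
    train: CineSeries, denoiser: Optional[Callable[[np.ndarray], np.ndarray]] = None
) -> CineSeries:
    """Apply an optional per-frame denoiser (default: identity) before training.

    A hook that changes the frame shape is rejected.
    """
    if denoiser is None:
        return train.copy()
    frames = np.empty_like(train.frames)
    for i, frame in enumerate(train.frames):
        out = np.asarray(denoiser(frame), dtype=np.complex128)
        if out.shape != frame.shape:
            raise ValueError("denoiser must preserve the frame shape")
        frames[i] = out
    return CineSeries(
        frames=frames,
        phase_labels=train.phase_labels.copy(),
        period_T=train.period_T,
        is_training=True,
        pixel_scale=train.pixel_scale,
    )


class CardiacMotionDictionary(BaseEstimator):
    """Estimator of the per-lag temporal covariance structure of a cine cycle.

    Parameters
    ----------
    pinv_tol : float
        Relative singular-value cutoff applied to ``C_0`` when forming
        ``pinv(C_0)`` (and hence the transitions).  Default 1e-10.
    denoiser : callable or None
        Optional per-frame denoising hook applied before estimation.

    Attributes (after ``fit``)
    --------------------------
    means_ : (N^2,) complex pixel temporal means.
    T_, N_ : training phases and grid size.
    rank_ : retained rank of ``C_0`` after the cutoff.
    """

    def __init__(self, pinv_tol: float = 1e-10, denoiser: Optional[Callable] = None):
        self.pinv_tol = pinv_tol
        self.denoiser = denoiser

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None) -> "CardiacMotionDictionary":
        """Estimate moments from a training cycle.

        ``X`` may be a :class:`CineSeries` or a complex array of shape
        (T, N, N).  Requires T >= 2.
        """
        if isinstance(X, CineSeries):
            series = preprocess_training(X, self.denoiser)
            frames = series.frames
        else:
            frames = np.asarray(X, dtype=np.complex128)
            if frames.ndim != 3 or frames.shape[1] != frames.shape[2]:
                raise ValueError("X must have shape (T, N, N)")
            if self.denoiser is not None:
                series = CineSeries(
                    frames=frames,
                    phase_labels=np.arange(1, frames.shape[0] + 1),
                    period_T=frames.shape[0],
                )
                frames = preprocess_training(series, self.denoiser).frames
        T, N = frames.shape[0], frames.shape[1]
        if T < 2:
            raise ValueError("training requires at least T=2 frames")
        _check_grid_cap(N)

        B = frames.reshape(T, N * N).T  # (n, T), row-major pixel order
        self.means_ = B.mean(axis=1)
        Y = B - self.means_[:, None]
        U, s, Vh = np.linalg.svd(Y, full_matrices=False)
        # pinv_tol is relative on the eigenvalues of C_0 = Y Y^H / T, i.e. s^2
        smax = s[0] if s.size else 0.0
        keep = s > np.sqrt(self.pinv_tol) * smax if smax > 0 else np.zeros_like(s, bool)
        self.rank_ = int(keep.sum())
        self.T_ = T
        self.N_ = N
        self._Y = Y
        self._U = U[:, keep]
        self._s = s[keep]
        self._Vh = Vh[keep]
        return self

    def _require_fit(self) -> None:
        if not hasattr(self, "means_"):
            raise RuntimeError("dictionary is not fitted")

    # -- covariances -------------------------------------------------------

    def _shifted(self, l: int) -> np.ndarray:
        idx = (np.arange(self.T_) + l) % self.T_
        return self._Y[:, idx]

    def cov_for_lag(self, l: int) -> np.ndarray:
        """Dense lag-``l`` covariance matrix ``C_l`` (signed lag, circular).

        ``C_{-l} = C_l^H`` holds exactly by the circular construction.
        """
        self._require_fit()
        if abs(l) >= self.T_:
            raise ValueError(f"|lag| must be < T = {self.T_}")
        if l < 0:
            return self.cov_for_lag(-l).conj().T
        return (self._shifted(l) @ self._Y.conj().T) / self.T_

    @property
    def cov_zero_diag_(self) -> np.ndarray:
        """Real diagonal of C_0 (per-pixel temporal variance)."""
        self._require_fit()
        return np.einsum("it,it->i", self._Y, self._Y.conj()).real / self.T_

    # -- transitions -------------------------------------------------------

    def transition_for_lag(self, l: int, first_step: bool = False) -> TransitionModel:
        """LMMSE transition for a signed lag: ``f = C_l pinv(C_0)``, ``b = mu - f mu``.

        ``first_step=True`` returns the identity transition with zero bias
        (used to seed the filter from the first training image).
        """
        self._require_fit()
        n = self.N_ * self.N_
        if first_step:
            return TransitionModel(b=np.zeros(n, dtype=np.complex128), lag=0, is_identity=True)
        if abs(l) >= self.T_:
            raise ValueError(f"|lag| must be < T = {self.T_}")
        # With Y = U S V^H:  C_l pinv(C_0) = Y_l V S^{-1} U^H  (rank-truncated)
        left = self._shifted(l) @ (self._Vh.conj().T / self._s)
        right = self._U.conj().T
        b = self.means_ - left @ (right @ self.means_)
        return TransitionModel(b=b, lag=l, left=left, right=right)

    # -- process covariances ----------------------------------------------

    def process_cov_two_stage(self) -> ProcessCov:
        """Two-stage Q: elementwise product of the identity with C_0 (its diagonal)."""
        return ProcessCov(diag=self.cov_zero_diag_, variant="two_stage")

    def process_cov_full(self) -> ProcessCov:
        """Non-diagonalized Q = C_0 (the ablation used to probe divergence)."""
        self._require_fit()
        C0 = self.cov_for_lag(0)
        return ProcessCov(diag=np.diag(C0).real, variant="full_c0", full=C0)


def process_cov_random_walk(train: CineSeries) -> ProcessCov:
    """Random-walk Q from T-1 successive difference images of the training scan.

    Diagonal entry (p, p) is the temporal variance of pixel p across the
    difference images; off-diagonals are taken as low-power and ignored.
    """
    frames = train.frames
    T, N = frames.shape[0], frames.shape[1]
    if T < 2:
        raise ValueError("need at least two frames to form difference images")
    _check_grid_cap(N)
    diffs = np.diff(frames.reshape(T, N * N), axis=0)  # (T-1, n)
    centered = diffs - diffs.mean(axis=0, keepdims=True)
    var = np.mean(np.abs(centered) ** 2, axis=0)
    return ProcessCov(diag=var, variant="random_walk")
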