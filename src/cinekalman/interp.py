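"""Per-step transitions when the test temporal resolution exceeds training.

Let ``V`` be the smallest phase transition the dictionary can model (the
temporal-resolution ratio, or more generally any lag for which a transition
``x_t = f_V x_{t-V} + b_V`` is available).  Frames in between are assumed to
fall *linearly* between the endpoints:

    x_{t-v} = ((V-v)/V) (x_t - x_{t-V}) + x_{t-V},      1 <= v <= V-1.

Substituting the base model yields a direct (anchor) prediction of any
intermediate phase from the anchor ``x_{t-V}``, and — by eliminating the
anchor — a per-step transition from phase ``t-v`` to ``t-v+1``:

    f_new = ((V-v+1)/V f_V + (v-1)/V I) pinv((V-v)/V f_V + v/V I)
    b_new = -f_new ((V-v)/V) b_V + ((V-v+1)/V) b_V

The inverse is a Moore-Penrose pseudoinverse: ``f_V`` is rank-deficient by
construction (rank <= T), so the chain is exact within the training span and
well-defined outside it.  ``v = V`` is additionally accepted, where the
pinv argument degenerates to the identity and the step reduces exactly to the
anchor step out of ``x_{t-V}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import TransitionModel

__all__ = ["InterpTransition", "anchor_prediction", "step_transition"]


@dataclass
class InterpTransition:
    """Dense per-step transition ``x -> f_new x + b_new`` for one (V, v)."""

    f: np.ndarray
    b: np.ndarray
    V: int
    v: int

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.f @ x + self.b

    def apply_cov(self, P: np.ndarray) -> np.ndarray:
        return self.f @ P @ self.f.conj().T

    @property
    def matrix(self) -> np.ndarray:
        return self.f


def anchor_prediction(fV: TransitionModel, V: int, v: int, x_anchor: np.ndarray) -> np.ndarray:
    """Predict the intermediate phase ``t-v`` directly from the anchor ``x_{t-V}``.

    Returns ``((V-v)/V f_V + v/V I) x + ((V-v)/V) b_V``.  ``v = 0`` formally
    reduces to the full-step prediction ``f_V x + b_V``.
    """
    if not (0 <= v <= V - 1):
        raise ValueError("v must satisfy 0 <= v <= V-1")
    a = (V - v) / V
    return a * (fV.apply(x_anchor) - x_anchor) + x_anchor


def step_transition(
    fV: TransitionModel, V: int, v: int, pinv_tol: float = 1e-10
) -> InterpTransition:
    """Per-step transition from phase ``t-v`` to ``t-v+1`` (1 <= v <= V).

    Built densely from the base transition; the pseudoinverse uses the
    dictionary's relative tolerance.  Identity base transitions short-circuit
    to the identity step.
    """
    if not (1 <= v <= V):
        raise ValueError("v must satisfy 1 <= v <= V")
    n = fV.n
    if fV.is_identity:
        return InterpTransition(
            f=np.eye(n, dtype=np.complex128),
            b=np.zeros(n, dtype=np.complex128),
            V=V,
            v=v,
        )
    f = fV.matrix
    eye = np.eye(n, dtype=np.complex128)
    A = ((V - v + 1) / V) * f + ((v - 1) / V) * eye
    if v == V:
        Bp = eye  # pinv of the identity
    else:
        Bm = ((V - v) / V) * f + (v / V) * eye
        Bp = np.linalg.pinv(Bm, rcond=pinv_tol)
    f_new = A @ Bp
    b_new = -f_new @ (((V - v) / V) * fV.b) + ((V - v + 1) / V) * fV.b
    return InterpTransition(f=f_new, b=b_new, V=V, v=v)
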