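"""Core containers for dynamic cardiac image series.

A :class:`CineSeries` is the unit of both training and ground-truth data: an
ordered stack of complex-valued N x N frames, each carrying an integer cardiac
phase label in ``1..period_T``.  Phase labels are 1-based, matching the
clinical "phase 1 ... phase T" convention for cine acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CineSeries", "ScenarioSpec"]


@dataclass
class CineSeries:
    """Ordered complex image frames with cardiac-phase bookkeeping.

    Parameters
    ----------
    frames : ndarray, complex, shape (M, N, N)
        Image frames, temporally ordered.
    phase_labels : ndarray, int, shape (M,)
        1-based cardiac phase of each frame, each in ``[1, period_T]``.
    period_T : int
        Number of phases in one cardiac cycle.
    is_training : bool
        Marks a series intended for dictionary estimation.
    pixel_scale : float
        Arbitrary intensity unit carried through rescaling (default 1.0).
    """

    frames: np.ndarray
    phase_labels: np.ndarray
    period_T: int
    is_training: bool = False
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.complex128)
        self.phase_labels = np.asarray(self.phase_labels, dtype=np.int64)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must have shape (M, N, N)")
        if self.frames.shape[0] < 1:
            raise ValueError("a series needs at least one frame")
        if self.phase_labels.shape != (self.frames.shape[0],):
            raise ValueError("one phase label per frame is required")
        if self.period_T < 1:
            raise ValueError("period_T must be >= 1")
        if np.any(self.phase_labels < 1) or np.any(self.phase_labels > self.period_T):
            raise ValueError("phase labels must lie in [1, period_T]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_size(self) -> int:
        return self.frames.shape[1]

    def copy(self) -> "CineSeries":
        return replace(self, frames=self.frames.copy(), phase_labels=self.phase_labels.copy())


@dataclass
class ScenarioSpec:
    """Recipe for assembling a multi-cycle test series from one cycle.

    ``kind`` selects the rhythm scenario:

    - ``"periodic"`` — the cycle repeats unchanged for ``n_cycles`` beats;
    - ``"arrhythmia"`` — one beat returns early to systole: the designated
      cycle keeps only phases ``1..truncate_at_phase``;
    - ``"rate_change"`` — one beat runs at a faster rate: the designated
      cycle keeps phases ``1, 1+skip_stride, 1+2*skip_stride, ...``;
    - ``"temporal_upsample"`` — test stays at full temporal resolution while
      the training side is decimated by ``upsample_factor`` (handled by
      :func:`cinekalman.phantom.decimate_training`).
    """

    kind: str = "periodic"
    n_cycles: int = 5
    truncate_at_phase: int = 0
    skip_stride: int = 2
    upsample_factor: int = 5
    modified_cycle: int = 2
    seed: int = 0

    _KINDS = ("periodic", "arrhythmia", "rate_change", "temporal_upsample")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.kind == "rate_change" and self.skip_stride < 2:
            raise ValueError("skip_stride must be >= 2")
        if self.kind == "temporal_upsample" and self.upsample_factor < 2:
            raise ValueError("upsample_factor must be >= 2")
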