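"""Undersampling patterns and the k-space measurement operator.

Three acquisition geometries are supported:

- **cartesian** — whole phase-encode lines (rows) of the N x N grid;
- **radial** — golden-angle spokes (111.246 deg increment) through the
  k-space center, continued across frames;
- **spiral** — a single Archimedean interleave from the center to the edge.

The measurement operator realizes ``E F``: a centered *orthonormal* 2-D DFT
followed by either mask selection (cartesian) or bilinear gridding
interpolation at the trajectory coordinates (non-cartesian), with the exact
conjugate-transpose as adjoint.  No density compensation is applied anywhere.
k-space coordinates are in cycles/pixel with ``|k| <= 0.5`` and the periodic
identification ``k = +0.5 == -0.5`` on the DFT grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .series import CineSeries

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "SamplingPattern",
    "MeasurementOperator",
    "KSpaceFrame",
    "cartesian_mask",
    "radial_trajectory",
    "spiral_trajectory",
    "build_operator",
    "measure_series",
]

GOLDEN_ANGLE_DEG = 111.246

#: oversampling ratio of readout samples per spoke relative to the grid size
RADIAL_OVERSAMPLING = 1.28


@dataclass
class SamplingPattern:
    """A per-frame undersampling geometry.

    Exactly one of ``mask`` (cartesian) or ``trajectory`` (radial/spiral) is
    set.  Trajectories are ``(m, 2)`` arrays of ``(kx, ky)`` in cycles/pixel.
    """

    kind: str
    N: int
    mask: Optional[np.ndarray] = None
    trajectory: Optional[np.ndarray] = None
    n_lines_or_spokes: int = 0
    samples_per_line: int = 0
    per_frame_variation: bool = False
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cartesian", "radial", "spiral"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.kind == "cartesian":
            if self.mask is None or self.mask.shape != (self.N, self.N):
                raise ValueError("cartesian pattern needs an N x N boolean mask")
        else:
            if self.trajectory is None or self.trajectory.ndim != 2 or self.trajectory.shape[1] != 2:
                raise ValueError("non-cartesian pattern needs an (m, 2) trajectory")
            if np.any(np.abs(self.trajectory) > 0.5 + 1e-12):
                raise ValueError("trajectory coordinates must satisfy |k| <= 0.5")

    @property
    def n_samples(self) -> int:
        if self.kind == "cartesian":
            return int(self.mask.sum())
        return self.trajectory.shape[0]


@dataclass
class KSpaceFrame:
    """Acquired complex samples for one frame plus their pattern."""

    samples: np.ndarray
    pattern: SamplingPattern
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.shape != (self.pattern.n_samples,):
            raise ValueError("sample count inconsistent with pattern")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _centered_fft2(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D DFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
    )


def _centered_ifft2(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
    )


def cartesian_mask(
    N: int,
    n_pe: int,
    *,
    variable_density: bool = True,
    center_fraction: float = 0.0,
    seed: int = 0,
    per_frame: bool = False,
    frame_index: int = 0,
) -> SamplingPattern:
    """Select ``n_pe`` whole phase-encode lines (rows) out of N.

    Variable-density mode always includes the DC line (row ``N//2``) plus a
    guaranteed center block of ``center_fraction * n_pe`` lines, and draws the
    remainder with probability decaying away from the center.  Uniform mode
    draws lines uniformly (DC still guaranteed).  With ``per_frame`` the drawn
    line set changes with ``frame_index`` while staying reproducible for a
    fixed seed.
    """
    if not (1 <= n_pe <= N):
        raise ValueError("n_pe must lie in [1, N]")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(frame_index,) if per_frame else ())
    )
    dc = N // 2
    rows = {dc}
    n_center = min(n_pe - 1, int(round(center_fraction * n_pe)))
    offset = 1
    while len(rows) < 1 + n_center:
        for cand in (dc - offset, dc + offset):
            if 0 <= cand < N and len(rows) < 1 + n_center:
                rows.add(cand)
        offset += 1
    n_extra = n_pe - len(rows)
    if n_extra > 0:
        remaining = np.setdiff1d(np.arange(N), sorted(rows))
        if variable_density:
            dist = np.abs(remaining - dc) / N
            w = (1.0 - dist) ** 4
            p = w / w.sum()
        else:
            p = None
        extra = rng.choice(remaining, size=n_extra, replace=False, p=p)
        rows.update(int(r) for r in extra)

    mask = np.zeros((N, N), dtype=bool)
    mask[sorted(rows), :] = True
    return SamplingPattern(
        kind="cartesian",
        N=N,
        mask=mask,
        n_lines_or_spokes=n_pe,
        samples_per_line=N,
        per_frame_variation=per_frame,
        frame_index=frame_index,
    )


def radial_trajectory(N: int, n_spokes: int, frame_index: int = 0) -> SamplingPattern:
    """Golden-angle radial spokes through the k-space center.

    Spoke angles continue the golden-angle progression *across frames*: the
    global spoke counter is ``frame_index * n_spokes + s``.  Each spoke is a
    full diameter carrying ``round(1.28 * N)`` equispaced samples.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    ns = int(round(RADIAL_OVERSAMPLING * N))
    radii = -0.5 + np.arange(ns) / ns  # [-0.5, 0.5), center hit when ns is even
    coords = []
    for s in range(n_spokes):
        g = frame_index * n_spokes + s
        theta = np.deg2rad(GOLDEN_ANGLE_DEG) * g
        coords.append(np.stack([radii * np.cos(theta), radii * np.sin(theta)], axis=1))
    traj = np.concatenate(coords, axis=0)
    return SamplingPattern(
        kind="radial",
        N=N,
        trajectory=traj,
        n_lines_or_spokes=n_spokes,
        samples_per_line=ns,
        per_frame_variation=True,
        frame_index=frame_index,
    )


def spiral_trajectory(
    N: int, n_rotations: int = 6, sampled_fraction: float = 0.08
) -> SamplingPattern:
    """Single Archimedean spiral interleave from the center to the k-space edge.

    The radius grows linearly with arc parameter while the angle sweeps
    ``n_rotations`` full turns; the sample count matches the cartesian-budget
    fraction of the N x N grid (default ~8%).
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    m = int(round(sampled_fraction * N * N))
    s = np.arange(m) / (m - 1)
    r = 0.5 * s
    theta = 2.0 * np.pi * n_rotations * s
    traj = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    return SamplingPattern(
        kind="spiral",
        N=N,
        trajectory=traj,
        n_lines_or_spokes=n_rotations,
        samples_per_line=m,
    )


def _bilinear_interp_matrix(traj: np.ndarray, N: int) -> sp.csr_matrix:
    """Sparse (m, N^2) matrix interpolating a Cartesian k-grid at trajectory points.

    Grid point (row i, col j) sits at k = ((j - N//2)/N, (i - N//2)/N); the
    interpolation is bilinear with periodic wrap (the DFT grid is periodic).
    """
    m = traj.shape[0]
    gx = traj[:, 0] * N + N // 2  # column coordinate
    gy = traj[:, 1] * N + N // 2  # row coordinate
    ix0 = np.floor(gx).astype(int)
    iy0 = np.floor(gy).astype(int)
    fx = gx - ix0
    fy = gy - iy0
    rows, cols, vals = [], [], []
    for dy, wy in ((0, 1.0 - fy), (1, fy)):
        for dx, wx in ((0, 1.0 - fx), (1, fx)):
            rows.append(np.arange(m))
            cols.append(((iy0 + dy) % N) * N + ((ix0 + dx) % N))
            vals.append(wy * wx)
    mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, N * N),
    )
    return mat


class MeasurementOperator:
    """Forward/adjoint realization of ``E F`` for one sampling pattern.

    ``forward`` maps an N x N image to the complex sample vector;
    ``adjoint`` is the exact conjugate-transpose (spreading with the same
    bilinear weights, then inverse DFT).  Built via :func:`build_operator`.
    """

    def __init__(self, pattern: SamplingPattern):
        self.pattern = pattern
        self.N = pattern.N
        if pattern.kind == "cartesian":
            self._interp = None
        else:
            self._interp = _bilinear_interp_matrix(pattern.trajectory, self.N)

    @property
    def n_samples(self) -> int:
        return self.pattern.n_samples

    def forward(self, image: np.ndarray) -> np.ndarray:
        if image.shape != (self.N, self.N):
            raise ValueError("image shape does not match operator grid")
        k = _centered_fft2(image)
        if self._interp is None:
            return k[self.pattern.mask]
        return self._interp @ k.ravel()

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        samples = np.asarray(samples, dtype=np.complex128)
        if samples.shape != (self.n_samples,):
            raise ValueError("sample vector length does not match pattern")
        if self._interp is None:
            k = np.zeros((self.N, self.N), dtype=np.complex128)
            k[self.pattern.mask] = samples
        else:
            k = (self._interp.conj().T @ samples).reshape(self.N, self.N)
        return _centered_ifft2(k)

    def apply_to_matrix(self, M: np.ndarray) -> np.ndarray:
        """Apply the forward operator to every column of an (N^2, k) matrix.

        Used by the Kalman update to form ``EF @ P`` without materializing a
        dense operator; the DFT runs batched over columns.
        """
        n = self.N * self.N
        if M.shape[0] != n:
            raise ValueError("matrix rows must equal N^2")
        imgs = M.T.reshape(-1, self.N, self.N)
        k = _centered_fft2(imgs)
        if self._interp is None:
            out = k[:, self.pattern.mask]
        else:
            out = (self._interp @ k.reshape(-1, n).T).T
        return np.ascontiguousarray(out.T)


def build_operator(pattern: SamplingPattern, N: Optional[int] = None) -> MeasurementOperator:
    """Construct the measurement operator ``E F`` for a pattern."""
    if N is not None and N != pattern.N:
        raise ValueError("grid size disagrees with pattern")
    return MeasurementOperator(pattern)


def measure_series(
    truth: CineSeries,
    patterns: Sequence[SamplingPattern] | SamplingPattern,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[KSpaceFrame]:
    """Simulate the acquisition: forward-project every frame and add noise.

    Complex white Gaussian noise with total variance ``noise_sigma**2`` per
    sample (std ``noise_sigma/sqrt(2)`` in each of the real and imaginary
    parts), deterministic for a fixed seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if isinstance(patterns, SamplingPattern):
        patterns = [patterns] * truth.n_frames
    if len(patterns) != truth.n_frames:
        raise ValueError("need one pattern per frame (or a single shared pattern)")
    rng = np.random.default_rng(seed)
    out = []
    for frame, pat in zip(truth.frames, patterns):
        op = build_operator(pat)
        z = op.forward(frame)
        if noise_sigma > 0:
            scale = noise_sigma / np.sqrt(2.0)
            z = z + scale * (rng.standard_normal(z.shape) + 1j * rng.standard_normal(z.shape))
        out.append(KSpaceFrame(samples=z, pattern=pat, noise_sigma=noise_sigma))
    return out
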