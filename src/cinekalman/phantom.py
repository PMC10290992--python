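"""Synthetic beating-heart cine phantom and rhythm-scenario assembly.

The phantom is a deliberately simple stand-in for a clinical short/long-axis
cine: a static thorax ellipse, a contracting annular "ventricle" whose cavity
shrinks smoothly into systole and refills toward end-diastole, and a
counter-phased "atrium" blob.  The ventricular inner radius follows a
two-harmonic Fourier modulation of the cardiac phase angle, so inter-frame
changes are small in diastole and large around systole — the anisotropic
temporal correlation a motion dictionary must face in real data.  A fixed
low-order polynomial phase map makes every frame genuinely complex without
confounding the motion.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .series import CineSeries, ScenarioSpec

__all__ = [
    "make_phantom_cycle",
    "make_phantom_pair",
    "build_scenario",
    "rescale_means",
    "decimate_training",
]


def _soft_disk(r: np.ndarray, radius: float, width: float) -> np.ndarray:
    """Smooth indicator of ``r < radius`` with edge width ``width``."""
    return 0.5 * (1.0 + np.tanh((radius - r) / width))


def make_phantom_cycle(
    N: int = 32,
    T: int = 20,
    *,
    ventricle_center: tuple[float, float] = (-0.22, 0.12),
    ventricle_inner_base: float = 0.26,
    contraction_amp: float = 0.09,
    second_harmonic_amp: float = 0.03,
    second_harmonic_phase: float = 0.7,
    wall_thickness: float = 0.13,
    atrium_center: tuple[float, float] = (0.34, -0.34),
    atrium_radius: float = 0.15,
    atrium_amp: float = 0.05,
    texture_amp: float = 0.03,
    seed: int = 0,
) -> CineSeries:
    """Generate one fully sampled synthetic cardiac cycle.

    Geometry lives in normalized coordinates ``[-1, 1]^2``.  Pixel magnitudes
    stay in [0, 1]; the result is deterministic for a fixed seed (the seed
    drives a static, smooth intensity texture over the thorax).

    Returns a :class:`CineSeries` of ``T`` complex frames with phase labels
    ``1..T`` and ``is_training=True`` left unset (callers decide).
    """
    if N < 8:
        raise ValueError("grid size N must be >= 8")
    if T < 4:
        raise ValueError("phases per cycle T must be >= 4")

    rng = np.random.default_rng(seed)
    ax = np.linspace(-1.0, 1.0, N, endpoint=False) + 1.0 / N
    X, Y = np.meshgrid(ax, ax, indexing="xy")
    edge = 1.5 / N  # sub-pixel soft edge so motion is smooth in time

    # static thorax with a seeded smooth texture
    r_thorax = np.sqrt((X / 0.95) ** 2 + (Y / 0.80) ** 2)
    thorax = _soft_disk(r_thorax, 1.0, edge)
    texture = gaussian_filter(rng.standard_normal((N, N)), sigma=N / 8.0)
    texture = texture_amp * texture / max(np.abs(texture).max(), 1e-12)
    base = thorax * (0.35 + texture)

    # time-invariant low-order polynomial phase map (radians)
    phase_map = 0.5 * X + 0.3 * Y + 0.4 * X * Y + 0.2 * X**2

    cx, cy = ventricle_center
    r_v = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    acx, acy = atrium_center
    r_a = np.sqrt((X - acx) ** 2 + (Y - acy) ** 2)

    frames = np.empty((T, N, N), dtype=np.complex128)
    for t in range(T):
        phi = 2.0 * np.pi * t / T
        # 2-harmonic radius modulation: cavity full near phase 1, smallest mid-cycle
        r_in = (
            ventricle_inner_base
            + contraction_amp * np.cos(phi)
            + second_harmonic_amp * np.cos(2.0 * phi + second_harmonic_phase)
        )
        r_out = 0.41 - 0.3 * (
            ventricle_inner_base + contraction_amp + second_harmonic_amp * np.cos(second_harmonic_phase) - r_in
        )
        cavity = _soft_disk(r_v, r_in, edge)
        myocardium = _soft_disk(r_v, r_out, edge) - cavity
        # atrium counter-phased: largest when the ventricular cavity is smallest
        r_atr = atrium_radius - atrium_amp * np.cos(phi)
        atrium = _soft_disk(r_a, r_atr, edge)

        mag = base * (1.0 - _soft_disk(r_v, r_out, edge)) * (1.0 - atrium)
        mag = mag + 0.85 * myocardium + 0.10 * cavity + 0.75 * atrium * thorax
        mag = np.clip(mag, 0.0, 1.0)
        frames[t] = mag * np.exp(1j * phase_map)

    labels = np.arange(1, T + 1)
    return CineSeries(frames=frames, phase_labels=labels, period_T=T)


def make_phantom_pair(N: int = 32, T: int = 20, seed: int = 0) -> tuple[CineSeries, CineSeries]:
    """Training cycle and a *distinct* test heartbeat from the same 'patient'.

    The test cycle shares the anatomy but carries beat-to-beat variability:
    slightly different contraction amplitude, baseline cavity size and atrial
    excursion, plus an independent texture draw.  This emulates acquiring the
    training cine and the test acquisition on separate heartbeats, so the
    dictionary faces persistent (not merely noisy) model mismatch.
    """
    train = make_phantom_cycle(N, T, seed=seed)
    train.is_training = True
    test = make_phantom_cycle(
        N,
        T,
        seed=seed + 1,
        contraction_amp=0.083,
        ventricle_inner_base=0.268,
        atrium_amp=0.055,
    )
    return train, test


def build_scenario(
    train: CineSeries, test_cycle: CineSeries, spec: ScenarioSpec
) -> tuple[CineSeries, np.ndarray]:
    """Assemble the ground-truth test series and phase schedule for a scenario.

    The test cycle is replicated ``n_cycles`` times; for ``arrhythmia`` the
    designated cycle is truncated after ``truncate_at_phase`` (early return to
    systole), for ``rate_change`` it keeps phases ``1, 1+stride, ...``
    (transient rate increase).  ``temporal_upsample`` leaves the test periodic
    at full resolution (the training side is decimated separately).

    Returns ``(test_series, phase_schedule)`` where the schedule records the
    1-based phase label of every test frame.
    """
    T = test_cycle.period_T
    if spec.kind != "temporal_upsample" and test_cycle.period_T != train.period_T:
        raise ValueError("primary scenarios require matching period_T in train and test")
    if test_cycle.n_frames != T:
        raise ValueError("test_cycle must contain exactly one cycle of T frames")

    full = np.arange(T)
    cycles: list[np.ndarray] = []
    for c in range(1, spec.n_cycles + 1):
        if spec.kind == "arrhythmia" and c == spec.modified_cycle:
            if not (1 <= spec.truncate_at_phase < T):
                raise ValueError("truncate_at_phase must lie in [1, T-1]")
            cycles.append(np.arange(spec.truncate_at_phase))
        elif spec.kind == "rate_change" and c == spec.modified_cycle:
            if spec.skip_stride >= T:
                raise ValueError("skip_stride must be < period_T")
            cycles.append(np.arange(0, T, spec.skip_stride))
        else:
            cycles.append(full)

    idx = np.concatenate(cycles)
    series = CineSeries(
        frames=test_cycle.frames[idx],
        phase_labels=test_cycle.phase_labels[idx],
        period_T=T,
        pixel_scale=test_cycle.pixel_scale,
    )
    return series, series.phase_labels.copy()


def rescale_means(
    test: CineSeries, train: CineSeries, mode: str = "training"
) -> CineSeries:
    """Rescale every test frame so its mean magnitude matches a reference.

    ``mode="training"`` matches each frame to the training frame of the same
    cardiac phase (contrast normalisation against automated intensity
    rescaling).  Test phases with no training counterpart — and every frame in
    ``mode="previous"`` — chain to the previous *already rescaled* test frame.
    Scaling is by a real positive scalar, so pixel phase is preserved.
    """
    if test.grid_size != train.grid_size:
        raise ValueError("test and train grid sizes must match")
    if mode not in ("training", "previous"):
        raise ValueError("mode must be 'training' or 'previous'")

    train_mean = {
        int(p): float(np.mean(np.abs(train.frames[i])))
        for i, p in enumerate(train.phase_labels)
    }
    out = test.frames.copy()
    prev_mean: float | None = None
    for i in range(test.n_frames):
        phase = int(test.phase_labels[i])
        if mode == "training" and phase in train_mean:
            ref = train_mean[phase]
        else:
            if prev_mean is None:
                # no counterpart and nothing before it: leave untouched
                prev_mean = float(np.mean(np.abs(out[i])))
                continue
            ref = prev_mean
        if ref <= 0.0:
            raise ValueError("reference frame has zero mean magnitude")
        cur = float(np.mean(np.abs(out[i])))
        if cur <= 0.0:
            raise ValueError("cannot rescale a frame with zero mean magnitude")
        out[i] = out[i] * (ref / cur)
        prev_mean = float(np.mean(np.abs(out[i])))
    return CineSeries(
        frames=out,
        phase_labels=test.phase_labels.copy(),
        period_T=test.period_T,
        is_training=test.is_training,
        pixel_scale=test.pixel_scale,
    )


def decimate_training(train: CineSeries, V: int) -> CineSeries:
    """Keep every ``V``-th training frame (phases 1, 1+V, 1+2V, ...).

    Models a training scan acquired at 1/V of the test temporal resolution.
    The decimated series is relabeled onto its own clock: ``period_T``
    becomes ``ceil(T/V)`` with phases ``1..ceil(T/V)``.
    """
    if V < 1:
        raise ValueError("V must be >= 1")
    if V == 1:
        return train.copy()
    if V >= train.period_T:
        raise ValueError("V must be smaller than the training period")
    keep = np.arange(0, train.n_frames, V)
    T_new = int(np.ceil(train.period_T / V))
    return CineSeries(
        frames=train.frames[keep],
        phase_labels=np.arange(1, keep.size + 1),
        period_T=T_new,
        is_training=True,
        pixel_scale=train.pixel_scale,
    )
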