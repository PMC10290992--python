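# cinekalman

Reconstruction toolkit for **dynamic cardiac MRI with irregular rhythm**,
built around a *predictive signal model*: an affine temporal prior learned
from a single fully sampled cardiac cycle of the same subject. The prior
drives two reconstruction frameworks for undersampled k-t acquisitions — a
**two-stage Kalman filter** and a **compressed-sensing solver with a
state-space consistency term** — and, unlike conventional cine rebinning,
needs no assumption that the heart beats periodically.

Intended users: MRI reconstruction researchers who want a tested, pure-Python
reference implementation of k-t prediction-based filtering, with a synthetic
beating-heart phantom so every stage runs and is verifiable without clinical
data.

## The model

From one training cycle of `T` complex `N×N` frames, each pixel is modeled as
a temporally wide-sense-stationary process (jointly WSS across pixels). The
**cardiac motion dictionary** holds the pixel means `μ` and the lag-`l`
covariance matrices `C_l` (circular in `l`, `C_{−l} = C_l^H`). The LMMSE
transition between any two cardiac phases separated by a signed lag `l` is

    x_t = f x_{t−1} + b,   f = C_l (C_0)^†,   b = μ − f μ,

with `†` the Moore–Penrose pseudoinverse (`C_0` has rank ≤ T−1 by
construction). Negative lags give backward transitions, which is how a single
training cycle models a return to systole (phase 50 → 1 implies `l = −49`;
an arrhythmic 30 → 1 implies `l = −29`; a rate-doubled beat keeping phases
1, 3, 5, … implies `l = 2`).

**Two-stage Kalman filter.** Stage one predicts the next frame with `(f, b)`
and propagates the covariance `P` with process noise `Q = diag(C_0)`; stage
two updates against acquired k-space `z_t = EF x_t + v_t`, where `EF` is a
centered orthonormal 2-D DFT plus mask selection (Cartesian) or
bilinear-gridding interpolation (golden-angle radial, spiral) with the exact
adjoint. A random-walk baseline (`f = I`, difference-image `Q`) is included.
When the test acquisition runs at `V×` the training temporal resolution,
per-step transitions for the intermediate phases are derived from the
linear-intermediate-frame construction (see `docs/methods.md`).

**Two-stage CS.** Solves
`min_X ‖HX−y‖² + λ_spar·TTV(X) + λ_ss·Σ‖f_m X_{m−1}+b_m−X_m‖²`
by Polak–Ribière nonlinear CG with backtracking line search; `λ_ss = 0`
recovers conventional temporal-TV CS exactly.

## Worked example

Reconstruct a simulated arrhythmic acquisition (early return to systole
after phase 12 of beat 2) from 3 golden-angle spokes per frame at N=32:

```bash
cinekalman report --config configs/primary-scenario-2.yaml --out scratch/scenario2
```

prints

```
two_stage:   {'mean_mse': 0.000237, 'per_cycle_mean_mse': [0.000242, 0.000223], 'verdict': 'convergent', ...}
random_walk: {'mean_mse': 0.000603, 'per_cycle_mean_mse': [0.000473, 0.000623], 'verdict': 'convergent', ...}
acceleration: 16.8
```

Read: both filters remain stable through the arrhythmic event (verdict
`convergent` from the MSE-variance trend diagnostic), but the predictive
signal model tracks the rhythm change ~2.5× more accurately than the
random-walk prior (mean squared error per pixel, image magnitudes ≤ 1), at a
radial acceleration rate of πN/(2·n_spokes) ≈ 16.8 relative to a fully
sampled radial scan. Reconstructions, per-frame MSE traces, and the summary
land in `scratch/scenario2/`.

The same pipeline is scriptable from Python:

```python
import cinekalman as ck

train, test = ck.phantom.make_phantom_pair(N=32, T=20, seed=0)
truth, schedule = ck.build_scenario(
    train, test, ck.ScenarioSpec(kind="arrhythmia", n_cycles=3, truncate_at_phase=12)
)
truth = ck.rescale_means(truth, train)
patterns = [ck.radial_trajectory(32, 3, frame_index=i) for i in range(truth.n_frames)]
kspace = ck.measure_series(truth, patterns, noise_sigma=0.01, seed=2)

model = ck.KalmanReconstructor(variant="two_stage", R_sigma2=1e-4, P0_sigma2=1e-3)
result = model.fit(train).predict(kspace, schedule, truth=truth)
print(result.mse_trace.mean())          # 0.000237
```

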