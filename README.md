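# stackdmd

Dynamic mode decomposition (DMD) for fluorescence-microscopy image stacks:
denoising, spectral mode analysis, prediction of unseen frames along the
stack axis, and decomposition of two-photon polarimetry sweeps.

## Who this is for

Microscopists and image analysts working with image *series* — time-lapse
movies, 3-D z-stacks, or polarization-angle sweeps — that are shot-noise
limited (multiphoton imaging of dim probes, STED, photon-counting
detectors).  DMD treats the series as a dynamical system and separates the
few modes that carry structure from the noise floor, with no training data
and no assumption of additive Gaussian noise.

## The method

A stack with frames x̄₁, …, x̄ₘ (each flattened to a pixel vector of length
n) is modeled as a linear progression x̄ₖ₊₁ = A·x̄ₖ, where A approximates the
Koopman operator of the underlying dynamics.  With the shifted snapshot
matrices X₁ = [x̄₁ … x̄ₘ₋₁] and X₂ = [x̄₂ … x̄ₘ], A is the least-squares
solution X₂·X₁⁺, realized without ever forming the n×n matrix:

1. truncated SVD X₁ ≈ U′ Σ′ V′*, rank r chosen by the optimal singular-value
   hard threshold (aspect-ratio-dependent coefficient × median singular
   value), a fixed rank, or an energy fraction;
2. reduced operator Ã = U′ᵀ X₂ V′ Σ′⁻¹ (r × r);
3. eigendecomposition Ã W = W Λ; exact DMD modes Φ = X₂ V′ Σ′⁻¹ W,
   unit-normalized;
4. amplitudes b by least squares against **all** snapshots through the
   Vandermonde structure (noise-robust), so that
   x̄ₖ ≈ Σⱼ φⱼ · λⱼᵏ⁻¹ · bⱼ, and continuous-axis exponents
   ωⱼ = ln(λⱼ)/Δ allow evaluation at fractional positions
   x(c) = Σⱼ φⱼ · e^{ωⱼ c} · bⱼ.

Real eigenvalues in (0, 1) are exponential decays (photobleaching); complex
conjugate pairs are oscillations (axial structure, orientation response).
When the spectral complexity exceeds the snapshot count (standing waves,
structure confined to central z-frames), plain DMD mixes modes.  **HoDMD**
(higher-order DMD, DMD-d) fixes this by a higher-order recurrence
x̄ₖ₊d = A₁x̄ₖ + … + A_d x̄ₖ₊d₋₁, implemented as DMD on delay-stacked reduced
snapshots X̃ₖ = [x̄ₖ; …; x̄ₖ₊d₋₁] with a two-stage SVD.

The package is organized as scikit-learn-style estimators (`DMD`, `HoDMD`
with `fit`, fitted attributes `modes_`, `eigenvalues_`, `omegas_`,
`amplitudes_`, `rank_`), thin functional wrappers (`fit_dmd`, `fit_hodmd`,
`reconstruct`, `predict_frames`, `analyze_polarimetry`, …), a synthetic
ground-truth generator (`make_phantom`, `make_psf`, `make_series`,
`add_poisson`), quality metrics (PSNR / MSE / SSIM / singular spectrum /
frame rank), and a `stackdmd` command-line tool (`denoise`, `interpolate`,
`polarimetry`, `phantom`, `eval`).

## Worked example

Denoise a shot-noise-limited, exponentially bleaching time series with
automatic rank selection:

```python
import numpy as np
from stackdmd import SeriesSpec, make_series, fit_dmd, psnr

# synthetic ground truth: bleaching decay 2%/frame, Poisson noise
noisy, truth = make_series(
    SeriesSpec(kind="bleach", m=40, background=0.0, photon_scale=2.0, seed=3)
)
model = fit_dmd(noisy, "auto")          # hard-threshold rank selection
print("retained modes:", model.rank_)
print("eigenvalue:", model.eigenvalues_[0])

rec = model.reconstruct()
dr = float(truth.data.max())
gain = [
    psnr(truth.frame(k), rec.frame(k), dr) - psnr(truth.frame(k), noisy.frame(k), dr)
    for k in range(1, 41)
]
print("min per-frame PSNR gain: %.1f dB" % min(gain))
```

Output:

```
retained modes: 1
eigenvalue: (0.9804475778515034+0j)
min per-frame PSNR gain: 14.0 dB
```

The hard threshold keeps exactly one mode; its real eigenvalue 0.980
matches the generative per-frame decay factor e^{−0.02} = 0.9802, and the
reconstruction beats the raw input by at least 14 dB PSNR on every frame.

The same models drive axial up-sampling: `downsample(stack, 3)` keeps every
third frame (40 → 14), `predict_frames(model, positions)` evaluates the
fitted model at the removed positions, and `evaluate_interpolation` scores
it frame-by-frame against linear interpolation.

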