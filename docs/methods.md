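# Methods

## Model

All decompositions operate on the snapshot matrix X ∈ ℝ^{n×m}: each frame
of the (x, y, m) data cube is flattened row-major over (x, y) into a column
of n = x·y pixels, ordered along the stack axis (time t, axial position z,
or polarization angle θ; spacing Δ, first-frame coordinate `origin`,
1-based frame k at coordinate origin + (k−1)·Δ).  The flattening convention
is fixed package-wide; any fixed bijection is equivalent because the
decomposition is permutation-invariant over pixels, but it must be
single-sourced so modes reshape back to images correctly.

Exact DMD assumes a linear propagator x̄ₖ₊₁ = A x̄ₖ (a finite-dimensional
Koopman approximation) and estimates its leading spectrum without forming
A: truncated SVD of X₁, reduced operator Ã = U′ᵀX₂V′Σ′⁻¹, eigenpairs
(λⱼ, wⱼ), exact modes φⱼ = X₂V′Σ′⁻¹wⱼ normalized to unit Euclidean norm.
Exact modes are preferred over projected modes (U′wⱼ) because they behave
better when the model is evaluated outside the span of X₁, which happens in
frame prediction.  Modes with λ = 0 produce a zero exact-mode column; the
projected mode is substituted there so normalization is defined.

Amplitudes solve min_b Σₖ ‖Φ diag(λ^{k−1}) b − x̄ₖ‖² over **all** m
snapshots (the noise-robust "optimal" amplitude fit), reduced to an r×r
linear system through the Vandermonde structure:
(Φ*Φ ∘ T̄Tᵀ) b = rowsum(T̄ ∘ Φ*X) with T_{jk} = λⱼᵏ.  A first-frame-only
fit is available for comparison; on consistent data the two agree.  Full
variable-projection refinement of the eigenvalues themselves is out of
scope (an extension point), as the amplitude-optimal linear fit already
captures the noise-robustness that matters at these problem sizes.

Continuous-axis exponents are ωⱼ = ln(λⱼ)/Δ on the principal branch.
Frequencies near the Nyquist limit (arg λ near ±π) are reported as-is, not
unwrapped.  λ = 0 modes get ω = NaN and are excluded from continuous
evaluation; at fractional powers their contribution is zero for k > 1.

Mode ordering is deterministic: descending |bⱼ|·|λⱼ|^{(m−1)/2} (an energy
proxy at mid-series), ties broken by descending |λⱼ| then ascending
arg(λⱼ).  This makes CSV exports reproducible run-to-run.

Reconstructions return the real part of the complex sum; the relative
Frobenius norm of the discarded imaginary part is available as a diagnostic
(`imaginary_residual`).  For real input the spectrum is closed under
conjugation, so the imaginary residual is at machine-precision level.

## Rank truncation

Three policies:

- `hard_threshold` (default, `rank="auto"`): keep singular values above
  ω(β)·median(σ), where β = min(n,m)/max(n,m) and ω(β) =
  λ*(β)/√μ_β with λ*(β) = sqrt(2(β+1) + 8β/((β+1)+sqrt(β²+14β+1))) and
  μ_β the median of the Marchenko–Pastur distribution, computed exactly by
  quadrature and root finding (cached per aspect ratio) rather than the
  published polynomial approximation.  This is the asymptotically optimal
  hard threshold for white noise of unknown level; the median singular
  value estimates the noise scale.  The threshold is floored at
  max(n,m)·ε·σ₁ so float fuzz of an exactly low-rank matrix never counts
  as signal, and the largest component is never discarded (r ≥ 1).
- `fixed`: r = min(requested, available).
- `energy`: smallest r whose cumulative squared singular values reach the
  requested fraction; `rank=1.0` therefore keeps everything above
  numerical precision.

All policies additionally cap r at the numerical rank of the matrix.  The
hard threshold assumes a plateau of noise singular values; on tiny or
noiseless matrices (e.g. a 2-row delay-embedded series) the median is not a
noise estimate and the threshold can under-select — use `fixed` or
`energy` there, as the standing-wave tests do.

## HoDMD (DMD-d)

Pipeline: (1) truncated SVD of the *full* snapshot matrix gives a spatial
basis U₁ of rank r₁ and reduced snapshots U₁ᵀX; (2) the reduced snapshots
are delay-embedded into an (r₁·d) × (m−d+1) matrix of stacked lags;
(3) standard DMD (second truncated SVD, reduced operator, eigendecomposition)
runs on the augmented matrix; (4) modes are lifted to pixel space as
U₁ · (leading r₁-block of the augmented eigenvector), unit-normalized —
using the leading block rather than an eigenvalue-weighted average of
blocks differs only by a unit-modulus factor that the amplitude fit
absorbs; (5) amplitudes are fitted against the original (non-augmented)
snapshots.  The same rank policy governs both SVD stages (the choice is
otherwise unconstrained; one policy keeps the interface simple).

The reduction to plain DMD at d = 1 is exact for consistent data.  The
returned rank may exceed m − 1, which is the point: delay embedding raises
the number of linearly independent basis functions, supplying the complex
conjugate pairs needed for non-monotonic axial profiles, standing waves,
and angle sweeps.  A warning fires when r₁·d exceeds the number of
augmented snapshots, the regime where the embedded fit starts chasing noise
(visible as spurious oscillatory pairs at large d).

Default delays when `delay="auto"`: 10 for z-stacks, 6 for polarimetry
sweeps, 1 (plain DMD) for time series — values found effective for each
axis semantic; always user-overridable.

## Reconstruction, prediction, interpolation baseline

Integer frame indices use the discrete form λ^{k−1} exactly; fractional
positions use e^{ω·(c−origin)}, which coincides with the discrete form at
acquired positions (tested to 1e−8).  Extrapolation beyond the acquired
coordinate range is refused by default: the linear-propagator assumption is
not trusted outside the data window.  Negative ripple in predictions is
kept (clipping is a display concern).

`downsample(stack, s)` keeps frames 1, 1+s, 1+2s, … (⌈m/s⌉ frames; a
40-frame stack at s = 3 keeps 14) and multiplies the step by s; a fitted
model on the coarse stack is then evaluated at the original fine
coordinates, i.e. at fractional powers λ^{q/s}.  `linear_interpolate` is
the pixel-wise baseline, bit-exact at existing frame coordinates.
`evaluate_interpolation` reports per-predicted-frame MSE and SSIM for both
methods plus integrated-intensity profiles.  Because the decomposition
denoises, its MSE against a *noisy* reference can exceed linear
interpolation's even when its output is cleaner; scoring against noise-free
truth (available for all synthetic data) avoids that ambiguity.

## Polarimetry analysis

An angle-indexed stack is decomposed (HoDMD d = 6 by default; d = 1 falls
back to plain DMD), and modes are classified by eigenvalue:
oscillatory if |Im λ|/|λ| > imag_tol (default 1e−3), otherwise constant if
||λ|−1| ≤ unit_tol (1e−3) or decaying if |λ| < 1.  The tolerances separate
Poisson jitter from genuine oscillation at the photon budgets the generator
simulates; both are configurable.  Conjugate pairs count as two modes.

Peak finding runs on the *oscillatory-modes-only* profile with the
oscillatory eigenvalues normalized to unit modulus: the background and
bleaching modes (and the damping factor |λ|^k inside the oscillatory modes
themselves) impose a monotonic trend that leaves a sawtooth step at the
0°/360° wrap and would register spurious maxima there.  What remains is the
stationary orientation response, whose strict circular local maxima (above
zero) are reported at sampled-angle precision — no sub-bin refinement.
Peaks closer than 45° (a quarter of the cos 2θ period) are merged, keeping
the higher, so a noisy plateau cannot split into two peaks.  A profile with
relative modulation below `flat_tol` (1e−3) is flagged flat (isotropic) and
yields no peaks.

`dft_compare` verifies the known limit: after subtracting each pixel's
temporal mean, the decomposition reduces to the discrete Fourier transform —
eigenvalues on the unit circle at angles 2πq/m.  This holds when the
centered snapshots are linearly independent; the comparison table reports
each eigenvalue's modulus, angle, nearest DFT bin, and mismatch.

## Synthetic ground truth

The generator provides every regime the package targets, each with a
noise-free truth and a Poisson-corrupted observation:

- **Sphere phantoms**: filled or shell spheres voxelized on a background;
  with zero background, frames beyond the spheres' axial extent are exactly
  zero (matrix rank 0), giving the sharp-transition worst case for low-rank
  decomposition.  The default benchmark phantom uses 5 filled spheres of
  radii 8–20 voxels in 128×128×100, seeded placement; no claim is made of
  reproducing any particular published phantom geometry.
- **Widefield PSF**: scalar-diffraction (Kirchhoff pupil-integral) defocus
  model, h(ρ,z) = ∫₀¹ J₀(kNAsρ)·exp(−iks²zNA²/2n)·s ds, intensity |h|²,
  normalized to unit sum.  Defaults NA 1.4, λ_em 520 nm, n 1.515, 25 nm xy
  / 50 nm z sampling (high-NA oil-immersion acquisition); all configurable.
  This is a paraxial scalar model — no vectorial high-NA effects, no STED
  depletion donut.
- **Convolution**: 3-D FFT convolution, zero-padded "same" output; tiny
  negative FFT ringing is clipped at zero.  Blur spreads structure into
  neighboring planes: empty-frame rank becomes positive and the singular
  spectrum decays faster, which is exactly why blurred stacks are easier to
  approximate at low rank.
- **Poisson corruption**: voxel ~ Poisson(photon_scale·I)/photon_scale;
  `photon_scale` sets the photon budget and hence the SNR (≈2 counts per
  intensity unit reproduces the shot-noise-limited look of dim multiphoton
  probes).  Zero intensity stays exactly zero; seeded and reproducible.
- **1-D-modulated series** (32×32 frames, m = 40 or 36, smooth seeded
  Gaussian-blob patterns, defaults chosen as realistic low-photon-count
  conditions): bleaching decay 2 %/frame; polarimetry modulation depth 0.8
  at 10° steps over 360°; a standing wave sin(x)cos(ωk); a Gaussian axial
  envelope (σ = 4 frames) emulating structure confined to central z-frames.
  The polarimetry model multiplies the bleaching envelope into the
  orientation response and adds a static background, and includes a smooth
  zero-mean orientation-disorder field (std 15°) — real membranes show
  orientational heterogeneity, and without it the modulated terms are
  scalar multiples of one spatial pattern, collapsing the snapshot matrix
  to rank 2 and making the four-mode structure unobservable to plain DMD.
  With disorder the noiseless matrix has rank exactly 4 (background,
  bleaching, one conjugate pair).  The standing-wave series carries a
  nonzero background by default, making its snapshot matrix rank 2.

What the generator does **not** emulate: detector read noise and gain,
drift/registration errors, depth-dependent aberrations, spatially varying
bleaching rates, and real organelle morphology.  Passing tests therefore
demonstrate correctness of the decomposition machinery and its behavior
under shot noise — not performance on any specific instrument's data.

## Numerical choices and problem sizes

Internal math is float64 throughout; TIFF input may be 8/16-bit unsigned or
32-bit float (converted without rescaling, single-channel only), output is
32-bit float, stored unclipped so round trips are bit-exact.  PSNR uses the
maximum of the reference stack as data range (reported as +inf for
identical frames); SSIM uses a Gaussian window σ = 1.5 with K1 = 0.01,
K2 = 0.03 and the reference's value range, shrinking the window for frames
smaller than 11 px.  Frame rank counts singular values above
max-dimension·ε·σ₁ (configurable, since reported rank values depend on the
tolerance).  Tests and the acceptance script run on 32×32–64×64 frames
with 30–40 frames per stack — sizes at which every pipeline completes in
seconds while exercising the same code paths as full-resolution data.

## Known limitations

- The linear-propagator model cannot represent dynamics whose spectral
  complexity exceeds the available basis; plain DMD on such data produces
  mode mixing by construction.  HoDMD extends the basis but requires
  choosing d manually (no automatic selection).
- The median-based hard threshold needs a genuine noise plateau; it is
  unreliable on very small matrices.
- Bleaching is modeled (and detected) as a single global exponential;
  spatially varying decay splits across additional modes.
- Polarimetry peak angles are reported at sampled-angle precision; the
  symmetric cos 2θ model always yields peak pairs 180° apart.
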