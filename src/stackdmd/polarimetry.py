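"""Two-photon polarimetry decomposition.

A polarimetry sweep records fluorescence while rotating the linear
polarization of a two-photon excitation laser; oriented probes respond with
an intensity modulated as cos 2(theta - theta0), riding on a photobleaching
decay and a static background.  Decomposing the angle-indexed stack
separates these contributions: oscillatory modes (complex-conjugate
eigenvalue pairs) carry the orientation signal, real eigenvalues slightly
below unity carry bleaching, and a unit real eigenvalue carries static
structure.  Peak angles of the reconstructed intensity-vs-angle profile
locate the probe orientation (two peaks 180 degrees apart for cos 2theta
symmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmd import DMD, RankPolicy, fit_dmd
from .hodmd import HoDMD, fit_hodmd
from .metrics import integrated_intensity
from .stack import AxisKind, ImageStack

__all__ = [
    "PolarimetryReport",
    "analyze_polarimetry",
    "classify_modes",
    "dft_compare",
]


@dataclass(frozen=True)
class PolarimetryReport:
    """Outcome of a polarimetry decomposition."""

    peak_angles: tuple[float, ...]  # degrees in [0, 360)
    n_oscillatory_modes: int
    n_decaying_modes: int
    n_constant_modes: int
    bleaching_eigenvalues: tuple[float, ...]  # real eigenvalues in (0, 1)
    angles: np.ndarray
    raw_profile: np.ndarray
    reconstructed_profile: np.ndarray
    model: DMD
    flat_profile: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_deg": self.angles,
                "raw_intensity": self.raw_profile,
                "reconstructed_intensity": self.reconstructed_profile,
            }
        )


def classify_modes(
    model: DMD, imag_tol: float = 1e-3, unit_tol: float = 1e-3
) -> tuple[int, int, int]:
    """Count (oscillatory, decaying, constant) modes.

    Oscillatory: |Im lambda| / |lambda| > imag_tol (each member of a
    conjugate pair counts).  The remaining (real-classified) modes are
    constant when ||lambda| - 1| <= unit_tol, decaying when |lambda| < 1.
    Growing real modes (|lambda| > 1 + unit_tol) fall in none of the bins.
    """
    lam = np.asarray(model.eigenvalues_)
    mag = np.abs(lam)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_imag = np.where(mag > 0, np.abs(lam.imag) / np.where(mag > 0, mag, 1), 0.0)
    oscillatory = rel_imag > imag_tol
    realish = ~oscillatory
    constant = realish & (np.abs(mag - 1.0) <= unit_tol)
    decaying = realish & ~constant & (mag < 1.0)
    return int(oscillatory.sum()), int(decaying.sum()), int(constant.sum())


def _circular_peaks(profile: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima with circular wrap-around, restricted
    to positive excursions of the (zero-mean) oscillation profile."""
    prev = np.roll(profile, 1)
    nxt = np.roll(profile, -1)
    is_peak = (profile > prev) & (profile >= nxt) & (profile > 0)
    return np.nonzero(is_peak)[0]


def _merge_close_peaks(
    peak_idx: np.ndarray, profile: np.ndarray, m: int, min_sep_frac: float = 0.125
) -> np.ndarray:
    """Greedily keep the highest peaks at circular distance >= min_sep_frac
    of the full sweep (default 45 degrees of 360: a quarter of the cos 2theta
    period), so a noisy plateau cannot register as two peaks."""
    min_sep = max(1, int(round(min_sep_frac * m)))
    kept: list[int] = []
    for i in sorted(peak_idx, key=lambda i: -profile[i]):
        if all(min(abs(i - j), m - abs(i - j)) >= min_sep for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def _oscillation_profile(model: DMD, imag_tol: float) -> np.ndarray:
    """Integrated intensity of the reconstruction restricted to the
    oscillatory modes.

    The orientation signal lives entirely in the complex-conjugate pairs;
    the non-oscillatory modes carry the bleaching envelope and the static
    background, whose monotonic trend leaves a sawtooth step at the circular
    wrap point that would register spurious profile maxima.  The oscillatory
    eigenvalues are additionally normalized to unit modulus (bleaching
    correction): their own |lambda| < 1 damping would otherwise tilt the
    angular profile the same way.
    """
    lam = model.eigenvalues_
    mag = np.abs(lam)
    osc = (np.abs(lam.imag) / np.where(mag > 0, mag, 1.0) > imag_tol) & (mag > 0)
    if not np.any(osc):
        return np.zeros(model.n_frames_)
    k = np.arange(model.n_frames_)
    unit = lam[osc] / mag[osc]
    powers = unit[:, None] ** k[None, :]
    part = model.modes_[:, osc] @ (model.amplitudes_[osc, None] * powers)
    return part.real.sum(axis=0)


def analyze_polarimetry(
    stack: ImageStack,
    d: int = 6,
    policy: RankPolicy | int | float | str = "auto",
    imag_tol: float = 1e-3,
    unit_tol: float = 1e-3,
    flat_tol: float = 1e-3,
) -> PolarimetryReport:
    """Decompose an angle-indexed stack and extract orientation peaks.

    Fits HoDMD with delay ``d`` (d=1 falls back to plain DMD), reconstructs
    the denoised stack, integrates intensity per angle, and reports local
    maxima (at sampled-angle precision, with circular wrap-around) of the
    oscillatory-modes-only profile — the bleaching and background modes are
    excluded from peak finding so their monotonic trend cannot masquerade as
    an orientation peak — together with the mode classification.  A stack
    whose reconstructed profile modulation stays below ``flat_tol`` relative
    to its mean is flagged flat and yields no peaks.
    """
    if stack.axis_kind != AxisKind.ANGLE:
        raise ValueError(f"expected an angle-indexed stack, got axis {stack.axis_kind}")
    if stack.n_frames < 4:
        raise ValueError("need at least four angular samples")
    model = fit_dmd(stack, policy) if d == 1 else fit_hodmd(stack, d, policy)
    recon = model.reconstruct()
    raw_profile = integrated_intensity(stack)
    rec_profile = integrated_intensity(recon)
    angles = np.mod(stack.coordinates, 360.0)

    mean = float(rec_profile.mean())
    flat = mean <= 0 or (rec_profile.max() - rec_profile.min()) / abs(mean) < flat_tol
    osc_profile = _oscillation_profile(model, imag_tol)
    peak_idx = np.array([], dtype=int) if flat else _circular_peaks(osc_profile)
    peak_idx = _merge_close_peaks(peak_idx, osc_profile, stack.n_frames)
    peak_angles = tuple(float(a) for a in np.sort(angles[peak_idx]))

    n_osc, n_dec, n_const = classify_modes(model, imag_tol, unit_tol)
    lam = model.eigenvalues_
    mag = np.abs(lam)
    bleaching = lam[
        (np.abs(lam.imag) / np.where(mag > 0, mag, 1) <= imag_tol)
        & (mag < 1.0 - unit_tol)
        & (lam.real > 0)
    ].real
    return PolarimetryReport(
        peak_angles=peak_angles,
        n_oscillatory_modes=n_osc,
        n_decaying_modes=n_dec,
        n_constant_modes=n_const,
        bleaching_eigenvalues=tuple(np.sort(bleaching)[::-1]),
        angles=angles,
        raw_profile=raw_profile,
        reconstructed_profile=rec_profile,
        model=model,
        flat_profile=bool(flat),
    )


def dft_compare(stack: ImageStack) -> pd.DataFrame:
    """Check the DFT limit of the decomposition.

    Subtracting the temporal mean of every pixel removes the non-oscillatory
    content, and the decomposition of the mean-subtracted series reduces to
    the discrete Fourier transform: all eigenvalues lie on the unit circle
    at the nontrivial roots of unity exp(2 pi i q / m).  Returns one row per
    eigenvalue with its modulus, angle, the nearest DFT bin angle, and the
    mismatch; a constant stack (all-zero after mean subtraction) raises the
    documented "no signal" error.
    """
    if stack.n_frames < 3:
        raise ValueError("need at least three frames")
    m = stack.n_frames
    centered = stack.with_data(stack.data - stack.data.mean(axis=2, keepdims=True))
    model = DMD(rank=m - 1).fit(centered)
    lam = model.eigenvalues_
    angles = np.angle(lam)
    dft_angles = 2.0 * np.pi * np.arange(m) / m
    dft_angles = np.angle(np.exp(1j * dft_angles[1:]))  # wrap to (-pi, pi]
    nearest = dft_angles[
        np.argmin(
            np.abs(np.angle(np.exp(1j * (angles[:, None] - dft_angles[None, :])))),
            axis=1,
        )
    ]
    mismatch = np.abs(np.angle(np.exp(1j * (angles - nearest))))
    return pd.DataFrame(
        {
            "eigenvalue_modulus": np.abs(lam),
            "eigenvalue_angle": angles,
            "nearest_dft_angle": nearest,
            "angle_mismatch": mismatch,
        }
    )
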