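"""Image-quality and diagnostic measures: PSNR, MSE, SSIM, integrated
intensity, singular-value spectrum, and per-frame matrix rank."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .stack import ImageStack, to_snapshot_matrix

__all__ = [
    "QualityReport",
    "psnr",
    "mse_ssim",
    "integrated_intensity",
    "singular_spectrum",
    "frame_rank",
    "quality_report",
]

#: SSIM constants recorded in every report
SSIM_PARAMS = {"gaussian_weights": True, "sigma": 1.5, "K1": 0.01, "K2": 0.03}


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio 10 log10(data_range^2 / MSE) in dB.

    Identical frames (MSE = 0) return +inf.
    """
    reference = np.asarray(reference)
    test = np.asarray(test)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch {reference.shape} vs {test.shape}")
    if not data_range > 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def mse_ssim(
    reference: np.ndarray, test: np.ndarray, data_range: Optional[float] = None
) -> tuple[float, float]:
    """Pixel-mean squared error and structural similarity of two frames.

    SSIM uses a Gaussian window (sigma 1.5) with K1=0.01, K2=0.03 and, unless
    given, the reference's value range as data_range.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch {reference.shape} vs {test.shape}")
    if data_range is None:
        data_range = float(reference.max() - reference.min())
        if data_range == 0.0:
            data_range = 1.0
    mse = float(np.mean((reference - test) ** 2))
    kwargs = dict(SSIM_PARAMS)
    side = min(reference.shape)
    if side < 11:  # Gaussian window needs 11 px; shrink for small frames
        kwargs["win_size"] = max(3, side - (1 - side % 2))
    ssim = float(
        structural_similarity(reference, test, data_range=data_range, **kwargs)
    )
    return mse, ssim


def integrated_intensity(stack: ImageStack) -> np.ndarray:
    """Per-frame sum of intensities; length m."""
    return stack.data.sum(axis=(0, 1))


def singular_spectrum(
    stack: ImageStack, plateau_eps: float = 0.05
) -> tuple[np.ndarray, Optional[int]]:
    """Full singular-value spectrum of the snapshot matrix, descending, and
    the plateau onset: first index (0-based) where the consecutive ratio
    s[i+1]/s[i] exceeds 1 - plateau_eps (None when the spectrum keeps
    decaying).  A noise floor shows up as such a plateau."""
    if stack.n_frames < 2:
        raise ValueError("need at least two frames for a singular spectrum")
    s = np.linalg.svd(to_snapshot_matrix(stack).matrix, compute_uv=False)
    nz = s > 0
    ratios = np.full(len(s) - 1, 0.0)
    valid = nz[:-1]
    ratios[valid] = s[1:][valid] / s[:-1][valid]
    onset = np.nonzero(ratios > 1.0 - plateau_eps)[0]
    return s, (int(onset[0]) if onset.size else None)


def frame_rank(frame: np.ndarray, tolerance: Optional[float] = None) -> int:
    """Numerical rank of a 2-D frame: singular values above
    tolerance * largest (default: max-dimension * machine epsilon)."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    s = np.linalg.svd(frame, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    tol = tolerance if tolerance is not None else max(frame.shape) * np.finfo(float).eps
    return int(np.sum(s > tol * s[0]))


@dataclass
class QualityReport:
    """Per-frame quality bundle of a reconstruction against a reference."""

    frame_index: np.ndarray
    psnr_db: np.ndarray
    mse: np.ndarray
    ssim: np.ndarray
    integrated_reference: np.ndarray
    integrated_test: np.ndarray
    singular_values: np.ndarray
    plateau_onset: Optional[int]
    ssim_params: dict = field(default_factory=lambda: dict(SSIM_PARAMS))
    frame_ranks: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame_index": self.frame_index,
                "psnr_db": self.psnr_db,
                "mse": self.mse,
                "ssim": self.ssim,
                "integrated_reference": self.integrated_reference,
                "integrated_test": self.integrated_test,
            }
        )
        if self.frame_ranks is not None:
            df["frame_rank"] = self.frame_ranks
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def quality_report(
    reference: ImageStack,
    test: ImageStack,
    data_range: Optional[float] = None,
    with_ranks: bool = False,
) -> QualityReport:
    """Frame-by-frame PSNR/MSE/SSIM of ``test`` against ``reference`` plus
    integrated-intensity profiles and the reference's singular spectrum.

    ``data_range`` defaults to the maximum of the reference stack.
    """
    if reference.data.shape != test.data.shape:
        raise ValueError(
            f"shape mismatch {reference.data.shape} vs {test.data.shape}"
        )
    if data_range is None:
        data_range = float(reference.data.max())
    m = reference.n_frames
    rows = []
    for k in range(1, m + 1):
        ref_f, test_f = reference.frame(k), test.frame(k)
        mse, ssim = mse_ssim(ref_f, test_f, data_range=data_range)
        rows.append((psnr(ref_f, test_f, data_range), mse, ssim))
    psnr_db, mse_v, ssim_v = (np.array(col) for col in zip(*rows))
    spectrum, onset = singular_spectrum(reference) if m >= 2 else (np.array([]), None)
    ranks = (
        np.array([frame_rank(test.frame(k)) for k in range(1, m + 1)])
        if with_ranks
        else None
    )
    return QualityReport(
        frame_index=np.arange(1, m + 1),
        psnr_db=psnr_db,
        mse=mse_v,
        ssim=ssim_v,
        integrated_reference=integrated_intensity(reference),
        integrated_test=integrated_intensity(test),
        singular_values=spectrum,
        plateau_onset=onset,
        frame_ranks=ranks,
    )
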