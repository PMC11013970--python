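"""Exact dynamic mode decomposition of image-stack snapshot matrices.

DMD approximates the linear (Koopman-type) operator ``A`` that advances one
snapshot to the next, ``x_{k+1} = A x_k``, from the data alone.  Because the
pixel dimension ``n`` vastly exceeds the number of frames, ``A`` is never
formed: a truncated SVD of ``X1`` yields a reduced ``r x r`` operator

    Atilde = U^T X2 V S^{-1}

whose eigenvalues ``lambda_j`` are shared with ``A``.  Exact DMD modes are
``phi_j = X2 V S^{-1} w_j`` (unit-normalized), and the series is reconstructed
as ``x_k = sum_j phi_j lambda_j^{k-1} b_j``.  Continuous-axis eigenvalues are
``omega_j = ln(lambda_j) / step`` (principal branch).

Rank truncation separates signal modes from the noise plateau of the singular
spectrum; the default policy is the optimal hard threshold for the matrix
aspect ratio with the noise level estimated from the median singular value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional

import numpy as np
from scipy import integrate, optimize
from sklearn.base import BaseEstimator

from .stack import (
    AxisKind,
    ImageStack,
    SnapshotMatrix,
    from_snapshot_matrix,
    shift_matrices,
    to_snapshot_matrix,
)

__all__ = [
    "RankPolicy",
    "SVDFactors",
    "ReducedOperator",
    "DMD",
    "truncated_svd",
    "reduced_operator",
    "eigendecompose",
    "compute_amplitudes",
    "continuous_eigenvalues",
    "optimal_hard_threshold_coefficient",
    "fit_dmd",
]


@dataclass(frozen=True)
class RankPolicy:
    """How many singular components to retain.

    mode='hard_threshold' (default): keep singular values above the optimal
    aspect-ratio-dependent hard threshold, with the noise level estimated
    from the median singular value.  mode='fixed' keeps ``fixed_rank``
    components (capped at what is available).  mode='energy' keeps the
    smallest r whose cumulative squared singular values reach
    ``energy_fraction`` of the total.  At least one component is always kept.
    """

    mode: Literal["hard_threshold", "fixed", "energy"] = "hard_threshold"
    fixed_rank: Optional[int] = None
    energy_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.fixed_rank is None or self.fixed_rank < 1:
                raise ValueError("fixed mode requires fixed_rank >= 1")
            if self.energy_fraction is not None:
                raise ValueError("fixed mode must not set energy_fraction")
        elif self.mode == "energy":
            if self.energy_fraction is None or not 0 < self.energy_fraction <= 1:
                raise ValueError("energy mode requires energy_fraction in (0, 1]")
            if self.fixed_rank is not None:
                raise ValueError("energy mode must not set fixed_rank")
        elif self.mode == "hard_threshold":
            if self.fixed_rank is not None or self.energy_fraction is not None:
                raise ValueError("hard_threshold mode takes no extra fields")
        else:
            raise ValueError(f"unknown rank policy mode {self.mode!r}")


@dataclass(frozen=True)
class SVDFactors:
    """Truncated SVD of X1 plus the full singular spectrum."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    retained_rank: int
    full_spectrum: np.ndarray


@dataclass(frozen=True)
class ReducedOperator:
    """The r x r similarity-reduced propagator Atilde = U^T X2 V S^{-1}."""

    Atilde: np.ndarray


# ---------------------------------------------------------------------------
# Optimal singular-value hard threshold (unknown noise level)
# ---------------------------------------------------------------------------


def _marchenko_pastur_median(beta: float) -> float:
    """Median of the Marchenko–Pastur distribution with aspect ratio beta."""
    lo = (1.0 - np.sqrt(beta)) ** 2
    hi = (1.0 + np.sqrt(beta)) ** 2

    def density(x):
        return np.sqrt((hi - x) * (x - lo)) / (2.0 * np.pi * beta * x)

    def cdf_minus_half(x):
        val, _ = integrate.quad(density, lo, x, limit=200)
        return val - 0.5

    return optimize.brentq(cdf_minus_half, lo + 1e-12, hi - 1e-12, xtol=1e-12)


@lru_cache(maxsize=128)
def optimal_hard_threshold_coefficient(beta: float) -> float:
    """Coefficient omega(beta) multiplying the median singular value.

    For an n x m matrix with aspect ratio beta = min(n,m)/max(n,m) and white
    noise of unknown level, the asymptotically optimal hard threshold is
    omega(beta) * median(singular values), with
    omega(beta) = lambda_*(beta) / sqrt(mu_beta), where lambda_* is the
    known-noise optimal coefficient and mu_beta the Marchenko–Pastur median.
    Evaluated exactly (quadrature + root finding), not via the published
    polynomial approximation.
    """
    if not 0 < beta <= 1:
        raise ValueError(f"aspect ratio beta must be in (0, 1], got {beta}")
    lam = np.sqrt(
        2.0 * (beta + 1.0)
        + 8.0 * beta / (beta + 1.0 + np.sqrt(beta**2 + 14.0 * beta + 1.0))
    )
    return float(lam / np.sqrt(_marchenko_pastur_median(beta)))


def _select_rank(s: np.ndarray, shape: tuple[int, int], policy: RankPolicy) -> int:
    if policy.mode == "fixed":
        return min(policy.fixed_rank, len(s))
    if policy.mode == "energy":
        cum = np.cumsum(s**2) / np.sum(s**2)
        return int(np.searchsorted(cum, policy.energy_fraction - 1e-15) + 1)
    # hard threshold
    n, m = shape
    if min(n, m) < 2:
        return 1
    beta = min(n, m) / max(n, m)
    tau = optimal_hard_threshold_coefficient(beta) * float(np.median(s))
    # never count float fuzz of an exactly low-rank matrix as signal
    tau = max(tau, s[0] * max(n, m) * np.finfo(float).eps)
    return max(1, int(np.sum(s > tau)))


def truncated_svd(X1: np.ndarray, policy: RankPolicy = RankPolicy()) -> SVDFactors:
    """Economy SVD of X1 truncated to the rank selected by ``policy``.

    The largest component is never discarded; an all-zero matrix is rejected
    ("no signal").
    """
    X1 = np.asarray(X1, dtype=np.float64)
    if X1.ndim != 2 or X1.shape[1] < 1:
        raise ValueError("X1 must be a 2-D matrix with at least one column")
    U, s, Vh = np.linalg.svd(X1, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("no signal: snapshot matrix is identically zero")
    r = _select_rank(s, X1.shape, policy)
    # never retain components below numerical precision of the spectrum
    num_rank = int(np.sum(s > s[0] * max(X1.shape) * np.finfo(float).eps))
    r = max(1, min(r, num_rank))
    return SVDFactors(
        U=U[:, :r], S=s[:r].copy(), V=Vh[:r].conj().T, retained_rank=r, full_spectrum=s
    )


def reduced_operator(svd: SVDFactors, X2: np.ndarray) -> ReducedOperator:
    """Project the propagator onto the leading left singular vectors:
    Atilde = U^T X2 V S^{-1} (real-transpose form; the data are real)."""
    if np.any(svd.S <= 0):
        raise np.linalg.LinAlgError(
            "zero singular value within retained rank: cannot invert Sigma"
        )
    Atilde = svd.U.T @ X2 @ svd.V / svd.S[np.newaxis, :]
    return ReducedOperator(Atilde=Atilde)


def eigendecompose(
    op: ReducedOperator, svd: SVDFactors, X2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of Atilde and exact DMD modes phi = X2 V S^{-1} W.

    Modes are normalized to unit Euclidean norm.  Output is deterministically
    ordered by descending |lambda|, ties by ascending arg(lambda); the model
    fit re-orders by mode energy once amplitudes are known.
    """
    if not np.all(np.isfinite(op.Atilde)):
        raise np.linalg.LinAlgError("reduced operator contains non-finite entries")
    try:
        eigvals, W = np.linalg.eig(op.Atilde)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"eigendecomposition of Atilde failed: {exc}") from exc
    modes = X2 @ svd.V @ np.diag(1.0 / svd.S) @ W
    norms = np.linalg.norm(modes, axis=0)
    # a zero mode column can only arise from lambda = 0; fall back to U W there
    zero = norms < np.finfo(float).eps * max(X2.shape)
    if np.any(zero):
        fallback = svd.U @ W[:, zero]
        modes[:, zero] = fallback
        norms = np.linalg.norm(modes, axis=0)
    modes = modes / norms[np.newaxis, :]
    order = np.lexsort((np.angle(eigvals), -np.abs(eigvals)))
    return eigvals[order], modes[:, order]


def compute_amplitudes(
    modes: np.ndarray,
    eigenvalues: np.ndarray,
    snap: SnapshotMatrix | np.ndarray,
    method: Literal["all_frames", "first_frame"] = "all_frames",
) -> np.ndarray:
    """Mode amplitudes b_j.

    method='first_frame': least-squares fit of Phi b = x_1.
    method='all_frames' (default, the noise-robust choice): least-squares fit
    of Phi diag(lambda^{k-1}) b over every snapshot, minimizing the error
    between the modes and all the frames.  Solved through the Vandermonde
    structure via the normal equations
    (Phi*Phi ∘ conj(T) T^T) b = rowsum(conj(T) ∘ Phi* X), T_{jk} = lambda_j^{k-1},
    which keeps the problem at r x r.
    """
    X = snap.matrix if isinstance(snap, SnapshotMatrix) else np.asarray(snap)
    if method == "first_frame":
        b, *_ = np.linalg.lstsq(modes, X[:, 0], rcond=None)
        return b
    if method != "all_frames":
        raise ValueError(f"unknown amplitude method {method!r}")
    m = X.shape[1]
    T = np.vander(eigenvalues, N=m, increasing=True)  # r x m, T[j,k] = lambda_j^k
    G = modes.conj().T @ modes
    A = G * (T.conj() @ T.T)
    c = ((modes.conj().T @ X) * T.conj()).sum(axis=1)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "rank-deficient mode basis: returning minimum-norm amplitudes",
            RuntimeWarning,
            stacklevel=2,
        )
    b, *_ = np.linalg.lstsq(A, c, rcond=None)
    return b


def continuous_eigenvalues(eigenvalues: np.ndarray, step: float) -> np.ndarray:
    """omega_j = log(lambda_j) / step on the principal branch.

    lambda = 0 modes carry no continuous-axis dynamics; their omega is NaN
    and they are excluded from continuous evaluation downstream.
    """
    if not step > 0:
        raise ValueError("step must be positive")
    lam = np.asarray(eigenvalues, dtype=complex)
    out = np.full(lam.shape, np.nan + 0j)
    nz = lam != 0
    out[nz] = np.log(lam[nz]) / step
    return out


def _energy_order(
    eigenvalues: np.ndarray, amplitudes: np.ndarray, m: int
) -> np.ndarray:
    """Deterministic mode ordering: descending |b|·|lambda|^{(m-1)/2}
    (mid-series energy proxy), ties by descending |lambda| then ascending arg."""
    energy = np.abs(amplitudes) * np.abs(eigenvalues) ** ((m - 1) / 2.0)
    return np.lexsort((np.angle(eigenvalues), -np.abs(eigenvalues), -energy))


class DMD(BaseEstimator):
    """Exact dynamic mode decomposition, scikit-learn style.

    Parameters
    ----------
    rank : 'auto', int, or float
        Truncation policy: 'auto' applies the optimal singular-value hard
        threshold; an int fixes the rank; a float in (0, 1] keeps that
        fraction of squared singular-value energy.
    amplitude_method : {'all_frames', 'first_frame'}
        'all_frames' fits amplitudes against every snapshot (noise robust);
        'first_frame' matches only the initial frame.
    step, origin : float
        Frame spacing and first-frame coordinate; overridden by the stack's
        own metadata when fitting an :class:`~stackdmd.stack.ImageStack`.

    Attributes (after fit)
    ----------------------
    modes_ : (n_pixels, rank_) complex ndarray — unit-norm exact DMD modes.
    eigenvalues_ : (rank_,) complex — discrete eigenvalues lambda_j.
    omegas_ : (rank_,) complex — continuous eigenvalues ln(lambda)/step.
    amplitudes_ : (rank_,) complex — mode amplitudes b_j.
    rank_ : int — retained rank.
    svd_ : SVDFactors — first (and only) truncated SVD.
    delay_ : int — 1 for plain DMD.
    """

    delay_ = 1

    def __init__(
        self,
        rank: int | float | str = "auto",
        amplitude_method: str = "all_frames",
        step: float = 1.0,
        origin: float = 0.0,
    ):
        self.rank = rank
        self.amplitude_method = amplitude_method
        self.step = step
        self.origin = origin

    # -- plumbing ----------------------------------------------------------
    def _rank_policy(self) -> RankPolicy:
        r = self.rank
        if r == "auto":
            return RankPolicy(mode="hard_threshold")
        if isinstance(r, (int, np.integer)):
            return RankPolicy(mode="fixed", fixed_rank=int(r))
        if isinstance(r, float):
            return RankPolicy(mode="energy", energy_fraction=r)
        if isinstance(r, RankPolicy):
            return r
        raise ValueError(f"rank must be 'auto', int, float, or RankPolicy; got {r!r}")

    def _coerce_snap(self, X) -> SnapshotMatrix:
        if isinstance(X, ImageStack):
            return to_snapshot_matrix(X)
        if isinstance(X, SnapshotMatrix):
            return X
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("X must be an ImageStack, SnapshotMatrix, or 2-D array")
        # sklearn orientation: rows are snapshots; transpose to n x m
        return SnapshotMatrix(
            matrix=arr.T,
            frame_shape=(1, arr.shape[1]),
            axis_kind=AxisKind.TIME,
            step=self.step,
            origin=self.origin,
        )

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        """Fit the decomposition.

        X may be an ImageStack, a SnapshotMatrix, or an (n_snapshots,
        n_pixels) array in scikit-learn orientation.
        """
        snap = self._coerce_snap(X)
        if snap.n_frames < 2:
            raise ValueError("at least two snapshots are required to fit DMD")
        if not np.all(np.isfinite(snap.matrix)):
            raise ValueError("snapshot matrix must be finite")
        pair = shift_matrices(snap)
        policy = self._rank_policy()
        svd = truncated_svd(pair.X1, policy)
        op = reduced_operator(svd, pair.X2)
        eigvals, modes = eigendecompose(op, svd, pair.X2)
        amps = compute_amplitudes(modes, eigvals, snap, self.amplitude_method)
        order = _energy_order(eigvals, amps, snap.n_frames)
        self.eigenvalues_ = eigvals[order]
        self.modes_ = modes[:, order]
        self.amplitudes_ = amps[order]
        self.rank_ = svd.retained_rank
        self.svd_ = svd
        self.step_ = float(snap.step)
        self.origin_ = float(snap.origin)
        self.omegas_ = continuous_eigenvalues(self.eigenvalues_, self.step_)
        self.frame_shape_ = snap.frame_shape
        self.axis_kind_ = snap.axis_kind
        self.n_frames_ = snap.n_frames
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "modes_"):
            raise AttributeError("estimator is not fitted; call fit first")

    def reconstruct_matrix(self, frame_indices=None) -> np.ndarray:
        """Complex snapshot matrix Sum_j phi_j lambda_j^{k-1} b_j at the given
        1-based (possibly fractional) frame indices; defaults to 1..m."""
        self._check_fitted()
        if frame_indices is None:
            frame_indices = np.arange(1, self.n_frames_ + 1)
        k = np.asarray(frame_indices, dtype=float)
        if np.any(k < 1):
            raise ValueError("frame indices are 1-based and must be >= 1")
        lam = self.eigenvalues_
        expo = k - 1.0
        if np.all(expo == np.round(expo)):
            powers = lam[:, None] ** expo[None, :].astype(int)
        else:
            # fractional powers need the continuous form; skip lambda=0 modes
            nz = lam != 0
            powers = np.zeros((lam.size, k.size), dtype=complex)
            powers[nz] = np.exp(
                np.outer(np.log(lam[nz]), expo)
            )
            powers[~nz, :] = 0.0
            powers[:, expo == 0] = 1.0
        return self.modes_ @ (self.amplitudes_[:, None] * powers)

    def reconstruct(self, frame_indices=None) -> ImageStack:
        """Real-part reconstruction as an ImageStack at integer or fractional
        1-based frame indices (default: all fitted frames)."""
        mat = self.reconstruct_matrix(frame_indices)
        snap = SnapshotMatrix(
            matrix=mat,
            frame_shape=self.frame_shape_,
            axis_kind=self.axis_kind_,
            step=self.step_,
            origin=self.origin_,
        )
        return from_snapshot_matrix(snap, real_part=True)

    def imaginary_residual(self, frame_indices=None) -> float:
        """Diagnostic: Frobenius norm of the discarded imaginary part,
        relative to the real part, of the reconstruction."""
        mat = self.reconstruct_matrix(frame_indices)
        denom = np.linalg.norm(mat.real)
        return float(np.linalg.norm(mat.imag) / denom) if denom > 0 else 0.0

    def transform(self, X) -> np.ndarray:
        """Project snapshots onto the mode basis (least-squares coordinates).

        Returns an (n_snapshots, rank_) complex array, making the estimator
        usable as an sklearn transformer for feature extraction.
        """
        self._check_fitted()
        snap = self._coerce_snap(X)
        coeffs, *_ = np.linalg.lstsq(self.modes_, snap.matrix, rcond=None)
        return coeffs.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_dmd(
    stack: ImageStack,
    policy: RankPolicy | int | float | str = "auto",
    amplitude_method: str = "all_frames",
) -> DMD:
    """Fit plain DMD to an image stack; returns the fitted estimator."""
    return DMD(rank=policy, amplitude_method=amplitude_method).fit(stack)
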