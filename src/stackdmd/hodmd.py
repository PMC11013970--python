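"""Higher-order DMD (DMD-d) via time-delay embedding.

Classical DMD can extract at most as many dynamic modes as there are
snapshots; when the spectral complexity of the data exceeds that (standing
waves, structure confined to a few central z-frames, angle sweeps with few
samples), the reconstruction mixes modes.  HoDMD assumes a higher-order
linear recurrence x_{k+d} = A_1 x_k + ... + A_d x_{k+d-1} and realizes it
spectrally by running standard DMD on delay-stacked snapshots
X~_k = [x_k; x_{k+1}; ...; x_{k+d-1}].

The implementation follows the DMD-d algorithm: a first SVD reduces the
pixel dimension to r1, the reduced snapshots are delay-embedded, a second
truncated SVD + eigendecomposition is performed on the augmented matrix, and
modes are lifted back to pixel space through the first-stage basis using the
leading d-block of each augmented eigenvector.  Amplitudes are then fitted
against the original (non-augmented) snapshots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dmd import (
    DMD,
    RankPolicy,
    compute_amplitudes,
    continuous_eigenvalues,
    eigendecompose,
    reduced_operator,
    truncated_svd,
    _energy_order,
)
from .stack import ImageStack

__all__ = ["AugmentedMatrix", "HoDMD", "delay_embed", "fit_hodmd"]

#: delays the source study found effective per stack-axis semantic
DEFAULT_DELAYS = {"z": 10, "angle": 6, "time": 1}


@dataclass(frozen=True)
class AugmentedMatrix:
    """Delay-embedded reduced snapshots: (r1*d) x (m-d+1), block row i holding
    the reduced snapshot sequence shifted by i-1."""

    matrix: np.ndarray
    delay: int
    reduced_dim: int


def delay_embed(reduced_snaps: np.ndarray, d: int) -> AugmentedMatrix:
    """Stack d time-lagged copies of the reduced snapshots.

    Input r1 x m; output (r1*d) x (m-d+1); d=1 is the identity embedding.
    """
    reduced_snaps = np.asarray(reduced_snaps)
    r1, m = reduced_snaps.shape
    if not 1 <= d <= m - 1:
        raise ValueError(f"delay d={d} out of admissible range 1..{m - 1} for m={m}")
    cols = m - d + 1
    blocks = [reduced_snaps[:, i : i + cols] for i in range(d)]
    return AugmentedMatrix(matrix=np.vstack(blocks), delay=d, reduced_dim=r1)


class HoDMD(DMD):
    """Delay-embedded DMD estimator.

    Parameters are those of :class:`~stackdmd.dmd.DMD` plus

    delay : int or 'auto'
        Number of stacked time lags d.  'auto' picks 10 for z-stacks, 6 for
        polarimetry angle sweeps, and 1 (plain DMD) for time series.  The
        same rank policy is applied to both SVD stages.

    Extra fitted attributes: ``delay_`` (the d used), ``rank1_`` (first-stage
    spatial rank), ``rank_`` (augmented rank, may exceed m-1).
    """

    def __init__(
        self,
        delay: int | str = "auto",
        rank: int | float | str = "auto",
        amplitude_method: str = "all_frames",
        step: float = 1.0,
        origin: float = 0.0,
    ):
        super().__init__(
            rank=rank, amplitude_method=amplitude_method, step=step, origin=origin
        )
        self.delay = delay

    def _resolve_delay(self, axis_kind, m: int) -> int:
        if self.delay == "auto":
            d = DEFAULT_DELAYS.get(getattr(axis_kind, "value", str(axis_kind)), 1)
            return min(d, m - 1)
        d = int(self.delay)
        return d

    def fit(self, X, y=None):
        snap = self._coerce_snap(X)
        m = snap.n_frames
        if m < 2:
            raise ValueError("at least two snapshots are required")
        d = self._resolve_delay(snap.axis_kind, m)
        if m <= d:
            raise ValueError(f"need m > d snapshots; got m={m}, d={d}")
        policy = self._rank_policy()

        # stage 1: spatial reduction of the full snapshot matrix
        svd1 = truncated_svd(snap.matrix, policy)
        r1 = svd1.retained_rank
        reduced = svd1.U.T @ snap.matrix  # r1 x m

        aug = delay_embed(reduced, d)
        if r1 * d > aug.matrix.shape[1]:
            warnings.warn(
                f"augmented dimension r1*d = {r1 * d} exceeds the {aug.matrix.shape[1]} "
                "augmented snapshots; the embedded fit may overfit noise "
                "(consider a smaller delay)",
                RuntimeWarning,
                stacklevel=2,
            )

        # stage 2: standard DMD on the augmented matrix
        X1a, X2a = aug.matrix[:, :-1], aug.matrix[:, 1:]
        if X1a.shape[1] < 1:
            raise ValueError("delay leaves no shifted snapshot pair")
        svd2 = truncated_svd(X1a, policy)
        op = reduced_operator(svd2, X2a)
        eigvals, aug_modes = eigendecompose(op, svd2, X2a)

        # lift: leading block of the augmented eigenvector, through stage-1 basis
        modes = svd1.U @ aug_modes[:r1, :]
        norms = np.linalg.norm(modes, axis=0)
        keep = norms > np.finfo(float).eps * max(snap.matrix.shape)
        modes = modes[:, keep] / norms[np.newaxis, keep]
        eigvals = eigvals[keep]

        amps = compute_amplitudes(modes, eigvals, snap, self.amplitude_method)
        order = _energy_order(eigvals, amps, m)
        self.eigenvalues_ = eigvals[order]
        self.modes_ = modes[:, order]
        self.amplitudes_ = amps[order]
        self.rank_ = int(eigvals.size)
        self.rank1_ = r1
        self.svd_ = svd1
        self.svd2_ = svd2
        self.delay_ = d
        self.step_ = float(snap.step)
        self.origin_ = float(snap.origin)
        self.omegas_ = continuous_eigenvalues(self.eigenvalues_, self.step_)
        self.frame_shape_ = snap.frame_shape
        self.axis_kind_ = snap.axis_kind
        self.n_frames_ = m
        return self


def fit_hodmd(
    stack: ImageStack,
    d: int | str = "auto",
    policy: RankPolicy | int | float | str = "auto",
    amplitude_method: str = "all_frames",
) -> HoDMD:
    """Fit HoDMD with delay d to an image stack; returns the fitted estimator."""
    return HoDMD(delay=d, rank=policy, amplitude_method=amplitude_method).fit(stack)
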