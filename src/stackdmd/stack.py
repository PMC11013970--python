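"""Image-stack container and snapshot-matrix plumbing.

A microscopy stack is a data cube with image coordinates ``(x, y)`` and a
third axis holding the independent variable of the series: time ``t`` for
time-lapse imaging, axial position ``z`` for 3-D stacks, or polarization
angle ``theta`` for two-photon polarimetry sweeps.  Every decomposition in
this package consumes the *snapshot matrix*: each frame is flattened
(row-major over ``(x, y)``) into a column vector of ``n = x * y`` entries,
and the ``m`` columns are ordered along the stack axis.

Frame ``k`` (1-based) sits at physical coordinate ``origin + (k - 1) * step``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import tifffile


class AxisKind(str, enum.Enum):
    """Semantic of the stack axis: time, axial position, or polarization angle."""

    TIME = "time"
    Z = "z"
    ANGLE = "angle"


@dataclass(frozen=True)
class ImageStack:
    """A single-channel image series.

    Parameters
    ----------
    data : ndarray, shape (x, y, m)
        Intensities in photon-count-like units, stored as float64.
    axis_kind : AxisKind
        Meaning of the third axis.
    step : float
        Spacing between consecutive frames (seconds, micrometers, or degrees).
    origin : float
        Coordinate of the first frame, in the same units as ``step``.
    """

    data: np.ndarray
    axis_kind: AxisKind = AxisKind.TIME
    step: float = 1.0
    origin: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"stack data must be 3-D (x, y, m), got shape {arr.shape}")
        if arr.shape[2] < 1:
            raise ValueError("stack must contain at least one frame")
        if not np.all(np.isfinite(arr)):
            raise ValueError("stack intensities must be finite")
        if not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "axis_kind", AxisKind(self.axis_kind))

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def frame(self, k: int) -> np.ndarray:
        """Return frame ``k`` (1-based)."""
        if not 1 <= k <= self.n_frames:
            raise IndexError(f"frame index {k} out of range 1..{self.n_frames}")
        return self.data[:, :, k - 1]

    def coordinate(self, k) -> np.ndarray:
        """Physical coordinate of (possibly fractional) frame index ``k``."""
        return self.origin + (np.asarray(k, dtype=float) - 1.0) * self.step

    @property
    def coordinates(self) -> np.ndarray:
        return self.coordinate(np.arange(1, self.n_frames + 1))

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return replace(self, data=data)


@dataclass(frozen=True)
class SnapshotMatrix:
    """Snapshot matrix ``X``: one flattened frame per column.

    ``matrix`` has shape ``(n, m)`` with ``n = x * y``; column ``k`` is
    frame ``k`` flattened in row-major (C) order over ``(x, y)``.
    """

    matrix: np.ndarray
    frame_shape: tuple[int, int]
    axis_kind: AxisKind = AxisKind.TIME
    step: float = 1.0
    origin: float = 0.0

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ShiftPair:
    """The shifted snapshot pair (X1, X2): frames 1..m-1 and 2..m."""

    X1: np.ndarray
    X2: np.ndarray


def read_stack(path, axis_kind, step: float, origin: float = 0.0) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Values are converted to float64 without rescaling: a 16-bit page with
    maximum 65535 yields a float frame with maximum 65535.  Multi-channel
    TIFFs are rejected; split channels upstream.
    """
    if not step > 0:
        raise ValueError(f"step must be positive, got {step} for {path}")
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(pages)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected single-channel pages, got array of shape {arr.shape}; "
            "multi-channel TIFFs must be split into one file per channel"
        )
    # tifffile yields (pages, x, y); move pages last
    data = np.moveaxis(arr.astype(np.float64), 0, -1)
    return ImageStack(data=data, axis_kind=AxisKind(axis_kind), step=step, origin=origin)


def write_stack(stack: ImageStack, path):
    """Write the stack as a multi-page 32-bit float TIFF.

    Values are stored as-is (no clipping, no rescaling), so a
    ``read_stack(write_stack(s))`` round trip is bit-exact in float32.
    """
    pages = np.moveaxis(stack.data.astype(np.float32), -1, 0)
    tifffile.imwrite(path, pages)
    return path


def to_snapshot_matrix(stack: ImageStack) -> SnapshotMatrix:
    """Reshape the (x, y, m) cube into the n x m snapshot matrix."""
    x, y = stack.frame_shape
    matrix = stack.data.reshape(x * y, stack.n_frames, order="C")
    return SnapshotMatrix(
        matrix=matrix,
        frame_shape=(x, y),
        axis_kind=stack.axis_kind,
        step=stack.step,
        origin=stack.origin,
    )


def from_snapshot_matrix(snap: SnapshotMatrix, real_part: bool = False) -> ImageStack:
    """Inverse of :func:`to_snapshot_matrix`.

    Complex matrices (reconstructions) are rejected unless ``real_part=True``,
    in which case only the real part is kept.
    """
    x, y = snap.frame_shape
    if snap.n_pixels != x * y:
        raise ValueError(
            f"matrix has {snap.n_pixels} rows but frame_shape {snap.frame_shape} "
            f"requires {x * y}"
        )
    matrix = snap.matrix
    if np.iscomplexobj(matrix):
        if not real_part:
            raise ValueError("complex matrix: pass real_part=True to keep Re only")
        matrix = matrix.real
    data = np.asarray(matrix, dtype=np.float64).reshape(x, y, snap.n_frames, order="C")
    return ImageStack(
        data=data, axis_kind=snap.axis_kind, step=snap.step, origin=snap.origin
    )


def shift_matrices(snap: SnapshotMatrix) -> ShiftPair:
    """Split the snapshot matrix into the shifted pair X1 (frames 1..m-1) and
    X2 (frames 2..m) whose linear relation X2 = A X1 defines the decomposition."""
    if snap.n_frames < 2:
        raise ValueError("at least two snapshots required")
    return ShiftPair(X1=snap.matrix[:, :-1], X2=snap.matrix[:, 1:])
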