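"""Model and report export: eigenvalue tables as CSV, modes as TIFF stacks."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmd import DMD
from .stack import ImageStack, write_stack

__all__ = ["eigenvalue_table", "export_eigenvalues", "export_modes"]


def eigenvalue_table(model: DMD) -> pd.DataFrame:
    """One row per mode: Re/Im of lambda and omega, |b|, plus the delay and
    retained rank(s) of the fit."""
    model._check_fitted()
    df = pd.DataFrame(
        {
            "re_lambda": model.eigenvalues_.real,
            "im_lambda": model.eigenvalues_.imag,
            "re_omega": model.omegas_.real,
            "im_omega": model.omegas_.imag,
            "abs_amplitude": np.abs(model.amplitudes_),
        }
    )
    df["delay"] = model.delay_
    df["rank"] = model.rank_
    if hasattr(model, "rank1_"):
        df["rank_stage1"] = model.rank1_
    return df


def export_eigenvalues(model: DMD, path) -> None:
    eigenvalue_table(model).to_csv(path, index=False)


def export_modes(model: DMD, real_path, imag_path) -> None:
    """Write the spatial modes, reshaped to frames, as two TIFF stacks
    (real and imaginary parts; one page per mode)."""
    model._check_fitted()
    x, y = model.frame_shape_
    cube = model.modes_.reshape(x, y, -1)
    real = ImageStack(
        data=np.ascontiguousarray(cube.real), axis_kind=model.axis_kind_, step=1.0
    )
    imag = ImageStack(
        data=np.ascontiguousarray(cube.imag), axis_kind=model.axis_kind_, step=1.0
    )
    write_stack(real, real_path)
    write_stack(imag, imag_path)
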