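"""Gradient calibration against a doped-water reference.

A doped-water sample (presaturation off, single dominant resonance) is
fitted with the current ``g_max``; since the diffusion weighting is
quadratic in the gradient amplitude, the corrective scale is
``sqrt(fitted_D / reference_D)``.  Refitting with ``g_max * scale``
reproduces the reference value.  The calibration absorbs any
gradient-shape or pulse-length convention mismatch between the
instrument (or simulator) and the fitting model.

The default reference is the doped-water diffusion coefficient of
1.91e-10 m^2/s at 298.15 K.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass

import numpy as np

from . import fitdosy, process, seqmodel
from .simulate import Pseudo2DDataset

__all__ = ["CalibrationResult", "calibrate_gradient", "REFERENCE_WATER_D"]

#: Doped-water reference diffusion coefficient, 1e-10 m^2/s, at 298.15 K.
REFERENCE_WATER_D = 1.91


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one gradient calibration."""

    scale: float  # multiplicative factor applied to g_max
    fitted_D_before: float  # 1e-10 m^2/s
    fitted_D_after: float  # 1e-10 m^2/s
    reference_D: float  # 1e-10 m^2/s
    sequence_kind: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        pathlib.Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "CalibrationResult":
        return cls(**json.loads(pathlib.Path(path).read_text()))


def _fit_dominant_peak(ds: Pseudo2DDataset, params, gw: float, target_points: int):
    matrix = process.apodize_and_transform(ds, gw=gw, target_points=target_points)
    matrix.params = params
    try:
        process.estimate_noise(matrix)
    except ValueError:
        pass
    r = matrix.rows[0].real
    i = int(np.argmax(r))
    height = float(r[i])
    floor = 20.0 * matrix.noise_sd if matrix.noise_sd else 0.0
    if height <= floor or height <= 0:
        raise CalibrationError("no dominant resonance found in the dataset")
    pick = fitdosy.Pick(ppm=float(matrix.ppm_axis[i]), index=i, height=height)
    intens, _flags = fitdosy.extract_decay(matrix, pick, window_ppm=0.01)
    ramp = seqmodel.gradient_ramp(params)
    b = seqmodel.b_value(params, ramp.amplitudes)
    return fitdosy.fit_stejskal_tanner(intens, b, fractions=ramp.fractions)


def calibrate_gradient(
    ds: Pseudo2DDataset,
    reference_D: float = REFERENCE_WATER_D,
    gw: float = 0.5,
    target_points: int | None = None,
) -> CalibrationResult:
    """Determine the gradient scale that maps the fitted water D onto
    the reference value.

    Parameters
    ----------
    ds:
        Time-domain doped-water dataset (single dominant resonance,
        presaturation off).
    reference_D:
        Target water diffusion coefficient in 1e-10 m^2/s.

    Raises
    ------
    CalibrationError
        If no dominant peak exists or the fit returns a non-positive D.
    ValueError
        If ``reference_D`` is not positive.
    """
    if not reference_D > 0:
        raise ValueError("reference_D must be positive")
    params = ds.params
    if target_points is None:
        target_points = 4 * ds.grid.points
    fit_before = _fit_dominant_peak(ds, params, gw, target_points)
    if not fit_before.ok or fit_before.D <= 0:
        raise CalibrationError(f"water decay fit failed: flags={fit_before.flags}")
    scale = math.sqrt(fit_before.D / reference_D)
    params_cal = params.with_(g_max=params.g_max * scale)
    fit_after = _fit_dominant_peak(ds, params_cal, gw, target_points)
    return CalibrationResult(
        scale=scale,
        fitted_D_before=fit_before.D,
        fitted_D_after=fit_after.D,
        reference_D=reference_D,
        sequence_kind=params.kind.value,
    )
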