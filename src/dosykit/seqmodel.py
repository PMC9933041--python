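"""Pulse-sequence parameterization and signal-attenuation forward model.

Three pulsed-field-gradient experiments are supported:

``traditional``
    Bipolar-pair stimulated-echo sequence with a longitudinal
    eddy-current delay; short diffusion delay, full 5-95% gradient ramp.
``relaxation_edited``
    Repeated double spin-echo train (``n_echo`` loops) ahead of a series
    of ``n_pairs`` gradient pulse pairs; the echo train attenuates
    fast-relaxing (macromolecular) signals before the diffusion encode.
``diffusion_edited``
    Same form as ``traditional`` but with a long diffusion delay and a
    restricted 25-95% ramp, so small molecules are already decayed in the
    first used increment and slowly diffusing macromolecules remain.

Units are SI throughout (seconds, T/m, rad s^-1 T^-1); gradient ramp
limits are percentages of ``g_max``.

Gradient pulse length convention
--------------------------------
``delta_total`` is the *summed* effective duration of a bipolar gradient
pulse pair (e.g. a "1.5 ms" per-lobe pair has ``delta_total = 3.0 ms``).
Use ``sequence_params(..., delta=x, delta_is_per_lobe=True)`` to convert
from a per-lobe figure.  Because the same convention is used by the
simulator and the fitter the choice is internally consistent; absolute
accuracy on instrument data is absorbed by gradient calibration
(:mod:`dosykit.calibrate`).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "GAMMA_1H",
    "SequenceKind",
    "PulseSequenceParams",
    "GradientRamp",
    "sequence_params",
    "gradient_ramp",
    "b_value",
    "transverse_time",
    "attenuation",
    "decay_curve",
    "decay_fraction",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_1H = 2.6752218744e8


class SequenceKind(str, enum.Enum):
    TRADITIONAL = "traditional"
    RELAXATION_EDITED = "relaxation_edited"
    DIFFUSION_EDITED = "diffusion_edited"


class InvalidParameterError(ValueError):
    """Raised when pulse-sequence parameters violate their invariants."""


@dataclass(frozen=True)
class PulseSequenceParams:
    """Full parameterization of one pseudo-2D diffusion experiment.

    Attributes
    ----------
    kind:
        Which of the three experiments this is.
    delta_total:
        Total effective gradient pulse duration of a bipolar pair (s).
    Delta:
        Diffusion delay (s).  For ``relaxation_edited`` this is the unit
        diffusion time separating consecutive gradient pulse pairs.
    tau:
        Short gradient-recovery delay (s).
    De:
        Eddy-current settling delay (s); metadata only.
    rd:
        Relaxation delay between transients (s); metadata only.
    n_echo:
        Echo-train loop count (``relaxation_edited`` only).
    n_pairs:
        Number of gradient pulse pair sets (``relaxation_edited`` only).
    n_pairs_effective:
        Effective multiplier of the unit diffusion time in the b-value.
        ``None`` means ``n_pairs - 1``.
    tau_echo:
        Half echo spacing of the editing train (s); the train's total
        transverse evolution time is ``n_echo * 4 * tau_echo``.
    ramp_min_pct, ramp_max_pct:
        Gradient ramp limits, percent of ``g_max``.
    n_increments, n_scans:
        Gradient steps and transients per step.
    g_max:
        Maximum gradient amplitude (T/m).  Superseded by calibration.
    gamma:
        Gyromagnetic ratio (rad s^-1 T^-1).
    shape_factor:
        Dimensionless effective-area factor for shaped gradient lobes.
    """

    kind: SequenceKind
    delta_total: float
    Delta: float
    tau: float = 3e-6
    De: float = 5e-3
    rd: float = 2.0
    n_echo: Optional[int] = None
    n_pairs: Optional[int] = None
    n_pairs_effective: Optional[float] = None
    # default gives a 112 ms editing train: a T2 = 20 ms macromolecule
    # is suppressed to 0.4% while a T2 = 0.5 s metabolite keeps ~80%
    tau_echo: float = 2.0e-3
    ramp_min_pct: float = 5.0
    ramp_max_pct: float = 95.0
    n_increments: int = 8
    n_scans: int = 8
    g_max: float = 0.535
    gamma: float = GAMMA_1H
    shape_factor: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.kind, SequenceKind):
            object.__setattr__(self, "kind", SequenceKind(self.kind))
        if not (0.0 < self.ramp_min_pct < self.ramp_max_pct <= 100.0):
            raise InvalidParameterError(
                f"ramp limits must satisfy 0 < min < max <= 100, got "
                f"{self.ramp_min_pct}..{self.ramp_max_pct}"
            )
        if self.delta_total <= 0 or self.Delta <= 0:
            raise InvalidParameterError("delta_total and Delta must be positive")
        if self.delta_total >= self.Delta:
            raise InvalidParameterError(
                f"delta_total ({self.delta_total}) must be < Delta ({self.Delta})"
            )
        for name in ("tau", "De", "rd", "tau_echo"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_increments < 2:
            raise InvalidParameterError("n_increments must be >= 2")
        if self.n_scans < 1:
            raise InvalidParameterError("n_scans must be >= 1")
        if self.g_max <= 0 or self.gamma <= 0 or self.shape_factor <= 0:
            raise InvalidParameterError("g_max, gamma, shape_factor must be > 0")
        if self.kind is SequenceKind.RELAXATION_EDITED:
            if self.n_echo is None or self.n_echo < 1:
                raise InvalidParameterError("relaxation_edited requires n_echo >= 1")
            if self.n_pairs is None or self.n_pairs < 2:
                raise InvalidParameterError("relaxation_edited requires n_pairs >= 2")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kind"] = self.kind.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PulseSequenceParams":
        d = dict(d)
        d["kind"] = SequenceKind(d["kind"])
        return cls(**d)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "PulseSequenceParams":
        return cls.from_dict(json.loads(s))

    def with_(self, **changes) -> "PulseSequenceParams":
        return replace(self, **changes)


_DEFAULTS = {
    SequenceKind.TRADITIONAL: dict(
        delta_total=3.0e-3,  # 2 x 1.5 ms bipolar lobes
        Delta=0.050,
        ramp_min_pct=5.0,
        ramp_max_pct=95.0,
    ),
    SequenceKind.RELAXATION_EDITED: dict(
        delta_total=0.8e-3,
        Delta=0.030,
        n_echo=14,
        n_pairs=6,
        ramp_min_pct=5.0,
        ramp_max_pct=95.0,
    ),
    SequenceKind.DIFFUSION_EDITED: dict(
        delta_total=3.0e-3,
        Delta=0.350,
        ramp_min_pct=25.0,
        ramp_max_pct=95.0,
    ),
}


def sequence_params(
    kind: SequenceKind | str,
    *,
    delta: Optional[float] = None,
    delta_is_per_lobe: bool = False,
    **overrides,
) -> PulseSequenceParams:
    """Build :class:`PulseSequenceParams` for ``kind`` with sane defaults.

    ``delta`` is an alternative spelling of ``delta_total``; with
    ``delta_is_per_lobe=True`` it is interpreted as the duration of one
    bipolar lobe and doubled.  Any other field may be overridden by
    keyword.
    """
    kind = SequenceKind(kind)
    cfg = dict(_DEFAULTS[kind])
    if delta is not None:
        cfg["delta_total"] = 2.0 * delta if delta_is_per_lobe else delta
    cfg.update(overrides)
    return PulseSequenceParams(kind=kind, **cfg)


@dataclass(frozen=True)
class GradientRamp:
    """Ordered gradient amplitudes for a pseudo-2D acquisition."""

    amplitudes: np.ndarray  # T/m, one per increment, strictly increasing
    fractions: np.ndarray  # same values as fraction of g_max (0-1)

    def __len__(self) -> int:
        return len(self.amplitudes)


def gradient_ramp(params: PulseSequenceParams) -> GradientRamp:
    """Linearly spaced gradient amplitudes from ramp_min to ramp_max.

    Endpoints are inclusive: the first increment sits at
    ``ramp_min_pct`` and the last at ``ramp_max_pct`` of ``g_max``.
    """
    if params.n_increments < 2:
        raise InvalidParameterError("n_increments must be >= 2")
    fractions = np.linspace(
        params.ramp_min_pct / 100.0, params.ramp_max_pct / 100.0, params.n_increments
    )
    return GradientRamp(amplitudes=fractions * params.g_max, fractions=fractions)


def _effective_diffusion_time(params: PulseSequenceParams) -> float:
    base = params.Delta - params.delta_total / 3.0 - params.tau / 2.0
    if base <= 0:
        raise InvalidParameterError("effective diffusion time must be positive")
    if params.kind is SequenceKind.RELAXATION_EDITED:
        n_eff = params.n_pairs_effective
        if n_eff is None:
            n_eff = params.n_pairs - 1
        return n_eff * base
    return base


def b_value(params: PulseSequenceParams, g) -> float | np.ndarray:
    """Diffusion weighting b (s m^-2) at gradient amplitude ``g`` (T/m).

    b = (gamma * shape_factor * g * delta_total)^2 * t_diff with
    t_diff = Delta - delta/3 - tau/2, multiplied by the effective number
    of gradient pulse pairs for the relaxation-edited train.  Exactly
    quadratic in g; b(0) = 0.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("gradient amplitude must be >= 0")
    q = params.gamma * params.shape_factor * g * params.delta_total
    b = q * q * _effective_diffusion_time(params)
    return float(b) if b.ndim == 0 else b


def transverse_time(params: PulseSequenceParams) -> float:
    """Total transverse-evolution time (s) relevant for T2 weighting.

    The stimulated-echo sequences spend only the short gradient/recovery
    windows transverse; the relaxation-edited train adds
    ``n_echo * 4 * tau_echo``.
    """
    base = 4.0 * params.tau + params.delta_total
    if params.kind is SequenceKind.RELAXATION_EDITED:
        return base + params.n_echo * 4.0 * params.tau_echo
    return base


def attenuation(
    params: PulseSequenceParams, D: float, T2: float, g: float
) -> float | np.ndarray:
    """Fraction of equilibrium signal surviving diffusion + T2 weighting.

    ``A = exp(-b(g) * D) * exp(-t_transverse / T2)``, 0 < A <= 1 for
    D >= 0, T2 > 0.  ``T2 = inf`` is accepted (no relaxation loss).
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if not T2 > 0:
        raise ValueError("T2 must be > 0")
    b = b_value(params, g)
    t_tr = transverse_time(params)
    relax = math.exp(-t_tr / T2) if math.isfinite(T2) else 1.0
    return np.exp(-b * D) * relax


def decay_curve(params: PulseSequenceParams, D: float, T2: float = math.inf) -> np.ndarray:
    """Per-increment attenuation over the gradient ramp."""
    ramp = gradient_ramp(params)
    return np.asarray(attenuation(params, D, T2, ramp.amplitudes))


def decay_fraction(curve: np.ndarray) -> float:
    """Relative signal decay over the experiment, 1 - last/first."""
    curve = np.asarray(curve, dtype=float)
    if curve[0] <= 0:
        raise ValueError("first-increment intensity must be positive")
    return 1.0 - float(curve[-1] / curve[0])
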