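"""Peak picking, decay extraction and Stejskal-Tanner fitting.

Peaks are picked on the first (lowest-gradient) increment, their
intensities tracked across the gradient ramp in a narrow window, and
each decay fitted to ``I(b) = I0 * exp(-D * b)``.  The fit is
initialized by log-linear regression and refined by nonlinear least
squares; the reported fitting error is the relative standard error of D
derived from the parameter covariance at the optimum.

Diffusion coefficients are reported in 1e-10 m^2/s.
"""

from __future__ import annotations

import hashlib
import math
import pathlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks as scipy_find_peaks

from . import seqmodel
from .process import SpectrumMatrix

__all__ = [
    "Pick",
    "DecayFit",
    "PeakEntry",
    "DosyPeakList",
    "pick_peaks",
    "extract_decay",
    "fit_stejskal_tanner",
    "build_peak_list",
    "synthesize_dosy_matrix",
]

D_UNIT = 1e-10


@dataclass(frozen=True)
class Pick:
    ppm: float
    index: int
    height: float


def pick_peaks(
    matrix: SpectrumMatrix,
    threshold_multiple: float = 5.0,
    min_height_frac: float = 1e-4,
) -> list[Pick]:
    """Local maxima of the first increment above the noise threshold.

    The threshold is ``threshold_multiple * noise_sd`` (plus a small
    floor, ``min_height_frac`` of the spectrum maximum, so that
    noiseless data do not pick numerical or truncation ripple).  The same threshold is required as peak
    prominence, which rejects noise ripples riding on the tails and
    shoulders of strong lines.  Points inside masked regions are
    excluded.  Returns an empty list when nothing qualifies.
    """
    r = matrix.rows[0].real
    thr = min_height_frac * float(np.max(np.abs(r))) if r.size else 0.0
    if matrix.noise_sd:
        thr = max(thr, threshold_multiple * matrix.noise_sd)
    idx, _props = scipy_find_peaks(r, height=thr, prominence=thr)
    picks = []
    for i in idx:
        if matrix.mask[i - 1 : i + 2].all():
            picks.append(Pick(ppm=float(matrix.ppm_axis[i]), index=int(i), height=float(r[i])))
    return picks


def extract_decay(
    matrix: SpectrumMatrix,
    pick: Pick,
    window_ppm: float = 0.005,
    measure: str = "max",
) -> tuple[np.ndarray, list[str]]:
    """Per-increment intensity of a pick within +-window_ppm/2.

    ``measure="max"`` takes the window maximum of the real part (the
    default, tracking peak intensity); ``"integral"`` sums the window.
    Returns the intensity vector and a list of flags; the window is
    truncated (and flagged) if it touches a masked region.
    """
    half = window_ppm / 2.0
    sel = np.abs(matrix.ppm_axis - pick.ppm) <= half
    if not np.any(sel):
        sel = np.zeros_like(sel)
        sel[pick.index] = True
    flags: list[str] = []
    if np.any(sel & ~matrix.mask):
        sel = sel & matrix.mask
        flags.append("window_truncated")
        if not np.any(sel):
            sel[pick.index] = True
    window = matrix.rows[:, sel].real
    if measure == "max":
        intens = window.max(axis=1)
    elif measure == "integral":
        intens = window.sum(axis=1)
    else:
        raise ValueError(f"unknown intensity measure {measure!r}")
    return np.asarray(intens, dtype=float), flags


@dataclass
class DecayFit:
    """Result of one Stejskal-Tanner fit; D in 1e-10 m^2/s."""

    D: float
    I0: float
    stderr_D: float
    relative_error: float
    residual_norm: float
    n_points_used: int
    ramp_indices_used: tuple
    flags: tuple = ()

    @property
    def ok(self) -> bool:
        return "fit_failed" not in self.flags


def _loglinear_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        return float(np.exp(intercept)), float(max(-slope, 0.0))
    # grid-search fallback for decays that dip non-positive early
    grid = np.concatenate([[0.0], np.logspace(-3, 2, 120)])
    best = (np.inf, 0.0, 0.0)
    for d in grid:
        basis = np.exp(-d * x)
        i0 = float(np.dot(basis, y) / np.dot(basis, basis))
        sse = float(np.sum((y - i0 * basis) ** 2))
        if sse < best[0]:
            best = (sse, i0, d)
    return best[1], best[2]


def fit_stejskal_tanner(
    intensities: Sequence[float],
    b_values: Sequence[float],
    fractions: Optional[Sequence[float]] = None,
    ramp_limits_pct: Optional[tuple[float, float]] = None,
) -> DecayFit:
    """Fit ``I(b) = I0 * exp(-D b)`` over the allowed ramp window.

    ``b_values`` are in SI (s m^-2); the fitted D is returned in
    1e-10 m^2/s.  When ``ramp_limits_pct`` is given, only increments
    whose gradient fraction (``fractions``, 0-1) lies within the limits
    (inclusive) are used; at least 3 usable points are required,
    otherwise the fit is flagged ``fit_failed``.  Negative D estimates
    are clamped to 0 and flagged ``clamped_negative``.
    """
    y = np.asarray(intensities, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if y.shape != b.shape:
        raise ValueError("intensities and b_values must have equal length")
    idx = np.arange(y.size)
    if ramp_limits_pct is not None:
        if fractions is None:
            raise ValueError("ramp_limits_pct requires gradient fractions")
        fr = np.asarray(fractions, dtype=float) * 100.0
        lo, hi = ramp_limits_pct
        keep = (fr >= lo - 1e-9) & (fr <= hi + 1e-9)
        idx = idx[keep]
    used = tuple(int(i) for i in idx)

    def failed(flag: str) -> DecayFit:
        return DecayFit(
            D=0.0,
            I0=float(y[idx[0]]) if idx.size else 0.0,
            stderr_D=math.inf,
            relative_error=math.inf,
            residual_norm=math.inf,
            n_points_used=int(idx.size),
            ramp_indices_used=used,
            flags=("fit_failed", flag),
        )

    if idx.size < 3:
        return failed("too_few_points")
    ysel, bsel = y[idx], b[idx]
    if ysel[0] <= 0:
        return failed("nonpositive_first_point")

    x = bsel * D_UNIT  # so the D parameter is directly in 1e-10 m^2/s
    i0_init, d_init = _loglinear_init(x, ysel)

    def model(xv, i0, d):
        return i0 * np.exp(-d * xv)

    try:
        popt, pcov = curve_fit(
            model, x, ysel, p0=[i0_init, d_init], maxfev=5000
        )
    except RuntimeError:
        return failed("no_convergence")
    i0_fit, d_fit = float(popt[0]), float(popt[1])
    stderr = float(np.sqrt(np.abs(pcov[1, 1])))
    resid = float(np.linalg.norm(ysel - model(x, *popt)))
    flags: list[str] = []
    if d_fit < 0:
        flags.append("clamped_negative")
        d_fit = 0.0
    rel = stderr / d_fit if d_fit > 0 else math.inf
    return DecayFit(
        D=d_fit,
        I0=i0_fit,
        stderr_D=stderr,
        relative_error=rel,
        residual_norm=resid,
        n_points_used=int(idx.size),
        ramp_indices_used=used,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class PeakEntry:
    ppm: float
    D: float  # 1e-10 m^2/s
    relative_error: float
    intensity: float
    flags: tuple = ()


@dataclass
class DosyPeakList:
    """Per-spectrum list of picked peaks with fitted D and fit error."""

    spectrum_id: str
    peaks: list
    params_hash: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    HEADER = "ppm\tD_1e-10_m2s\trel_error\tintensity\tflags"

    def write(self, path) -> None:
        path = pathlib.Path(path)
        lines = [
            "# dosykit peak list v1",
            f"# spectrum_id: {self.spectrum_id}",
            f"# params_hash: {self.params_hash}",
            self.HEADER,
        ]
        for p in self.peaks:
            flags = ",".join(p.flags) if p.flags else "ok"
            lines.append(
                f"{p.ppm!r}\t{p.D!r}\t{p.relative_error!r}\t{p.intensity!r}\t{flags}"
            )
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> tuple["DosyPeakList", list[str]]:
        """Parse the columnar dialect; returns (list, warnings).

        Malformed data lines are reported with their line number and
        skipped, never silently dropped.
        """
        path = pathlib.Path(path)
        spectrum_id = path.stem
        params_hash = ""
        peaks: list[PeakEntry] = []
        warnings: list[str] = []
        header_seen = False
        for ln, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("spectrum_id:"):
                    spectrum_id = body.split(":", 1)[1].strip()
                elif body.startswith("params_hash:"):
                    params_hash = body.split(":", 1)[1].strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != cls.HEADER.replace(" ", ""):
                    raise ValueError(
                        f"{path}: unrecognized peak-list header at line {ln}: {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                warnings.append(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
                continue
            try:
                ppm, d, rel, inten = (float(v) for v in parts[:4])
            except ValueError:
                warnings.append(f"{path}:{ln}: unparseable number in {line!r}")
                continue
            flags = () if parts[4] in ("ok", "") else tuple(parts[4].split(","))
            peaks.append(PeakEntry(ppm, d, rel, inten, flags))
        if not header_seen:
            raise ValueError(f"{path}: missing peak-list header")
        return cls(spectrum_id=spectrum_id, peaks=peaks, params_hash=params_hash), warnings


def build_peak_list(
    matrix: SpectrumMatrix,
    spectrum_id: str = "spectrum",
    threshold_multiple: float = 5.0,
    window_ppm: float = 0.005,
    ramp_limits_pct: Optional[tuple[float, float]] = None,
    measure: str = "max",
) -> DosyPeakList:
    """Pick -> extract -> fit every peak of a processed matrix.

    Failed fits are kept with their flags rather than dropped, so peak
    accounting (retention statistics) stays truthful.
    """
    params = matrix.params
    ramp = seqmodel.gradient_ramp(params)
    b = seqmodel.b_value(params, ramp.amplitudes)
    picks = pick_peaks(matrix, threshold_multiple=threshold_multiple)
    # coincident picks (same digital point) keep the taller one
    by_index: dict[int, Pick] = {}
    for p in picks:
        if p.index not in by_index or p.height > by_index[p.index].height:
            by_index[p.index] = p
    entries: list[PeakEntry] = []
    for p in sorted(by_index.values(), key=lambda q: q.ppm):
        intens, flags = extract_decay(matrix, p, window_ppm=window_ppm, measure=measure)
        fit = fit_stejskal_tanner(
            intens, b, fractions=ramp.fractions, ramp_limits_pct=ramp_limits_pct
        )
        entries.append(
            PeakEntry(
                ppm=p.ppm,
                D=fit.D,
                relative_error=fit.relative_error,
                intensity=p.height,
                flags=tuple(flags) + fit.flags,
            )
        )
    params_hash = hashlib.sha256(params.to_json(sort_keys=True).encode()).hexdigest()[:12]
    return DosyPeakList(spectrum_id=spectrum_id, peaks=entries, params_hash=params_hash)


def synthesize_dosy_matrix(
    peaklist: DosyPeakList,
    ppm_axis: np.ndarray,
    d_range: tuple[float, float] = (0.0, 12.0),
    n_d: int = 256,
    d_width_floor: float = 0.05,
    ppm_width: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a peak list as a 2D (D x ppm) display matrix.

    Each peak becomes a 2D Gaussian at (ppm, D); its D-dimension sd is
    ``max(stderr_D, d_width_floor)``.  Columns are normalized so the
    integral over D equals the peak intensity.  Display only - never
    used for quantification.
    """
    if not peaklist.peaks:
        raise ValueError("peak list is empty")
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    d_axis = np.linspace(d_range[0], d_range[1], n_d)
    dd = d_axis[1] - d_axis[0]
    out = np.zeros((n_d, ppm_axis.size))
    for p in peaklist.peaks:
        sd_d = max(
            p.relative_error * p.D if math.isfinite(p.relative_error) else d_width_floor,
            d_width_floor,
        )
        gd = np.exp(-0.5 * ((d_axis - p.D) / sd_d) ** 2)
        gd /= gd.sum() * dd
        gp = np.exp(-0.5 * ((ppm_axis - p.ppm) / ppm_width) ** 2)
        if gp.sum() > 0:
            gp = gp / gp.max()
        out += p.intensity * gd[:, None] * gp[None, :]
    return out, d_axis, ppm_axis
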