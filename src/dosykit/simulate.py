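"""Synthetic biofluid phantoms and pseudo-2D diffusion datasets.

Two phantom families are provided with known ground truth:

* a urine-like phantom: >= 30 small-molecule multiplets over 0.5-9 ppm
  plus a TSP reference singlet at 0.00 ppm;
* a plasma-like phantom: named small molecules (alanine, lactate,
  valine, glucose) plus broad macromolecule envelopes (protein, lipid,
  lipoprotein) with short T2 and small diffusion coefficients.

Each spectral line is an exponentially damped complex oscillation
(Lorentzian lineshape); increment ``i`` of the pseudo-2D matrix is
scaled by :func:`dosykit.seqmodel.attenuation` at the i-th ramp
amplitude.  Complex white Gaussian noise with standard deviation
``noise_sigma / sqrt(n_scans)`` is added per increment.

Diffusion coefficients on :class:`Species` are expressed in
1e-10 m^2/s (the display unit used throughout the package); they are
converted to SI internally.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import seqmodel
from .seqmodel import PulseSequenceParams, SequenceKind, sequence_params

__all__ = [
    "Multiplet",
    "Species",
    "Phantom",
    "SimulationGrid",
    "Pseudo2DDataset",
    "build_urine_phantom",
    "build_plasma_phantom",
    "build_doped_water_phantom",
    "simulate_dataset",
]

D_UNIT = 1e-10  # m^2/s per displayed diffusion unit


def binomial_intensities(n_lines: int) -> list[float]:
    """First-order multiplet line intensities (Pascal's triangle), sum 1."""
    row = [1.0]
    for _ in range(n_lines - 1):
        row = [a + b for a, b in zip([0.0] + row, row + [0.0])]
    total = sum(row)
    return [v / total for v in row]


@dataclass(frozen=True)
class Multiplet:
    """A first-order multiplet: ``n_lines`` lines spaced ``j_hz`` apart."""

    center_ppm: float
    j_hz: float
    n_lines: int
    intensities: tuple = None  # relative line intensities, sum to 1
    weight: float = 1.0  # relative weight of this multiplet within its species

    def __post_init__(self):
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        ints = self.intensities
        if ints is None:
            ints = tuple(binomial_intensities(self.n_lines))
        else:
            ints = tuple(float(v) for v in ints)
            if len(ints) != self.n_lines:
                raise ValueError("intensities length must equal n_lines")
            s = sum(ints)
            if not np.isclose(s, 1.0, atol=1e-9):
                ints = tuple(v / s for v in ints)
        object.__setattr__(self, "intensities", ints)

    def line_offsets_hz(self) -> np.ndarray:
        k = np.arange(self.n_lines, dtype=float)
        return (k - (self.n_lines - 1) / 2.0) * self.j_hz

    def line_ppm(self, sf_mhz: float) -> np.ndarray:
        return self.center_ppm + self.line_offsets_hz() / sf_mhz


@dataclass(frozen=True)
class Species:
    """One molecular component of a phantom.

    ``D`` is in 1e-10 m^2/s; ``T2`` in seconds; ``linewidth`` the
    Lorentzian full width at half maximum in Hz; ``amplitude`` an
    arbitrary concentration unit; ``presat`` a multiplicative
    suppression factor (only the water species uses < 1).
    """

    name: str
    multiplets: tuple
    D: float
    T2: float
    linewidth: float
    amplitude: float
    presat: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "multiplets", tuple(self.multiplets))
        if self.D < 0:
            raise ValueError(f"{self.name}: D must be >= 0")
        if not self.T2 > 0:
            raise ValueError(f"{self.name}: T2 must be > 0")
        if not self.linewidth > 0:
            raise ValueError(f"{self.name}: linewidth must be > 0")

    def line_table(self, sf_mhz: float) -> list[tuple[float, float]]:
        """(ppm, amplitude) for every line of every multiplet."""
        out = []
        for m in self.multiplets:
            for ppm, rel in zip(m.line_ppm(sf_mhz), m.intensities):
                out.append((float(ppm), self.amplitude * m.weight * rel))
        return out


def _species_to_dict(sp: Species) -> dict:
    d = dataclasses.asdict(sp)
    return d


def _species_from_dict(d: dict) -> Species:
    d = dict(d)
    d["multiplets"] = tuple(Multiplet(**m) for m in d["multiplets"])
    return Species(**d)


@dataclass
class Phantom:
    """Ground-truth description of a synthetic biofluid."""

    name: str
    species: list
    water: Species
    reference: Optional[Species] = None
    noise_sigma: float = 0.0

    def __post_init__(self):
        if "water" not in self.water.name:
            raise ValueError("water species must be named '*water*'")
        for sp in self.species:
            if "water" in sp.name:
                raise ValueError("only one water entry allowed (use .water)")

    def all_species(self) -> list[Species]:
        out = list(self.species)
        out.append(self.water)
        if self.reference is not None:
            out.append(self.reference)
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": [_species_to_dict(s) for s in self.species],
            "water": _species_to_dict(self.water),
            "reference": None
            if self.reference is None
            else _species_to_dict(self.reference),
            "noise_sigma": self.noise_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Phantom":
        return cls(
            name=d["name"],
            species=[_species_from_dict(s) for s in d["species"]],
            water=_species_from_dict(d["water"]),
            reference=None
            if d.get("reference") is None
            else _species_from_dict(d["reference"]),
            noise_sigma=d.get("noise_sigma", 0.0),
        )


@dataclass(frozen=True)
class SimulationGrid:
    """Digitization of the acquisition: points, width, field, carrier."""

    points: int = 16384
    sw_ppm: float = 12.0
    sf_mhz: float = 600.13
    carrier_ppm: float = 4.7
    temperature_k: float = 300.0

    @property
    def sw_hz(self) -> float:
        return self.sw_ppm * self.sf_mhz

    @property
    def dwell(self) -> float:
        return 1.0 / self.sw_hz

    def ppm_bounds(self) -> tuple[float, float]:
        half = self.sw_ppm / 2.0
        return (self.carrier_ppm - half, self.carrier_ppm + half)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class Pseudo2DDataset:
    """Gradient-incremented complex FID/spectrum matrix + metadata.

    ``meta`` carries the pulse-sequence parameters, the digitization
    grid, the domain flag (``"time"`` or ``"frequency"``) and anything a
    downstream stage needs; ``matrix`` is complex128 with one row per
    gradient increment.
    """

    def __init__(
        self,
        meta: dict,
        matrix: np.ndarray,
        ground_truth: Optional[Phantom] = None,
    ):
        matrix = np.asarray(matrix, dtype=np.complex128)
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-D [increments x points]")
        n_inc = meta["params"]["n_increments"]
        if matrix.shape[0] != n_inc:
            raise ValueError(
                f"matrix has {matrix.shape[0]} rows but params specify "
                f"{n_inc} increments"
            )
        self.meta = meta
        self.matrix = matrix
        self.ground_truth = ground_truth

    @property
    def params(self) -> PulseSequenceParams:
        return PulseSequenceParams.from_dict(self.meta["params"])

    @property
    def grid(self) -> SimulationGrid:
        g = self.meta["grid"]
        return SimulationGrid(
            points=g["points"],
            sw_ppm=g["sw_ppm"],
            sf_mhz=g["sf_mhz"],
            carrier_ppm=g["carrier_ppm"],
            temperature_k=g["temperature_k"],
        )

    @property
    def domain(self) -> str:
        return self.meta["domain"]

    # -- directory format: meta.json + data.bin (+ ground_truth.json) ---
    def save(self, path) -> None:
        """Write ``meta.json`` + little-endian float64 ``data.bin``.

        The binary layout is interleaved real/imaginary, row-major
        [increments x points]; the round trip is bit-exact.
        """
        path = pathlib.Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = dict(self.meta)
        meta["shape"] = list(self.matrix.shape)
        (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        inter = np.empty(self.matrix.shape + (2,), dtype="<f8")
        inter[..., 0] = self.matrix.real
        inter[..., 1] = self.matrix.imag
        (path / "data.bin").write_bytes(inter.tobytes())
        if self.ground_truth is not None:
            (path / "ground_truth.json").write_text(
                json.dumps(self.ground_truth.to_dict(), indent=1)
            )

    @classmethod
    def load(cls, path) -> "Pseudo2DDataset":
        path = pathlib.Path(path)
        meta = json.loads((path / "meta.json").read_text())
        shape = tuple(meta["shape"])
        raw = np.frombuffer((path / "data.bin").read_bytes(), dtype="<f8")
        inter = raw.reshape(shape + (2,))
        matrix = inter[..., 0] + 1j * inter[..., 1]
        gt_path = path / "ground_truth.json"
        gt = (
            Phantom.from_dict(json.loads(gt_path.read_text()))
            if gt_path.exists()
            else None
        )
        return cls(meta=meta, matrix=matrix, ground_truth=gt)


# ----------------------------------------------------------------------
# phantom builders
# ----------------------------------------------------------------------

def _default_water(amplitude: float = 60.0, presat: float = 0.01) -> Species:
    return Species(
        name="water",
        multiplets=(Multiplet(center_ppm=4.70, j_hz=0.0, n_lines=1),),
        D=23.0,
        T2=0.25,
        linewidth=6.0,
        amplitude=amplitude,
        presat=presat,
    )


def build_urine_phantom(seed: int = 0, n_species: int = 16) -> Phantom:
    """Urine-like phantom: small molecules only, TSP reference at 0 ppm.

    Deterministic for a fixed seed.  Each species carries two multiplets
    (so >= 30 multiplets at the default size) with centers in
    0.5-9.0 ppm outside the water region, D drawn in 4-10 (1e-10 m^2/s)
    and T2 in 0.3-1.5 s.
    """
    rng = np.random.default_rng(seed)
    centers: list[float] = []

    def draw_center() -> float:
        while True:
            c = float(rng.uniform(0.5, 9.0))
            if 4.35 <= c <= 5.1:  # keep clear of the pruned water region
                continue
            if all(abs(c - o) > 0.06 for o in centers):
                centers.append(c)
                return c

    species = []
    for i in range(n_species):
        mults = []
        for _ in range(2):
            c = draw_center()
            n_lines = int(rng.integers(1, 5))
            j = float(rng.uniform(3.0, 9.0)) if n_lines > 1 else 0.0
            mults.append(Multiplet(center_ppm=c, j_hz=j, n_lines=n_lines))
        species.append(
            Species(
                name=f"metab_{i:02d}",
                multiplets=tuple(mults),
                D=float(rng.uniform(4.0, 10.0)),
                T2=float(rng.uniform(0.3, 1.5)),
                linewidth=float(rng.uniform(1.2, 2.5)),
                amplitude=float(rng.uniform(0.8, 2.0)),
            )
        )
    tsp = Species(
        name="tsp",
        multiplets=(Multiplet(center_ppm=0.0, j_hz=0.0, n_lines=1),),
        D=5.0,
        T2=1.1,
        linewidth=1.3,
        amplitude=1.5,
    )
    # noise level chosen so the first-increment TSP SNR of the default
    # 8-scan traditional experiment is in the high-600s
    return Phantom(
        name="urine",
        species=species,
        water=_default_water(),
        reference=tsp,
        noise_sigma=0.16,
    )


# Glucose proton multiplets (ppm, J in Hz, lines, weight); all share one D.
_GLUCOSE_MULTIPLETS = (
    (5.23, 3.8, 2, 0.10),  # anomeric H1 doublet, weak on purpose
    (3.25, 8.0, 2, 0.15),
    (3.41, 6.0, 2, 0.15),
    (3.49, 5.0, 2, 0.15),
    (3.55, 5.5, 2, 0.15),
    (3.72, 5.5, 2, 0.15),
    (3.84, 4.0, 2, 0.15),
)

#: Reported consistent glucose diffusion coefficient, 1e-10 m^2/s.
GLUCOSE_D = 7.20


def build_plasma_phantom(seed: int = 0) -> Phantom:
    """Plasma-like phantom: small molecules + macromolecule envelopes.

    All glucose multiplets share ``D = 7.20``; protein envelope lines
    have D in 0.72-0.83 and T2 <= 0.025 s, lipids at 5.15-5.4 ppm have
    D in 0.05-0.40, lipoproteins at 0.84/1.25 ppm have D < 0.1.
    """
    rng = np.random.default_rng(seed)
    species: list[Species] = []

    def mk(name, mults, D, T2, lw, amp):
        species.append(
            Species(
                name=name,
                multiplets=tuple(mults),
                D=D,
                T2=T2,
                linewidth=lw,
                amplitude=amp,
            )
        )

    mk(
        "glucose",
        [Multiplet(c, j, n, weight=w) for (c, j, n, w) in _GLUCOSE_MULTIPLETS],
        GLUCOSE_D,
        0.50,
        1.5,
        3.0,
    )
    mk("alanine", [Multiplet(1.47, 7.2, 2)], 6.80, 0.60, 1.5, 0.9)
    mk(
        "lactate",
        [Multiplet(1.30, 7.0, 2, weight=0.75), Multiplet(4.14, 7.0, 4, weight=0.25)],
        7.40,
        0.70,
        1.5,
        1.1,
    )
    mk(
        "valine",
        [Multiplet(0.98, 7.0, 2, weight=0.5), Multiplet(1.03, 7.0, 2, weight=0.5)],
        6.20,
        0.60,
        1.5,
        0.55,
    )

    # broad protein envelope: overlapping wide Lorentzians in the
    # 2.4-3.0 / 3.7-4.1 ppm humps and the aromatic region; kept away
    # from the lipoprotein signals so those decays stay unmixed
    small_lines = [
        ppm for sp in species for (ppm, _a) in sp.line_table(600.13)
    ]
    protein_regions = [
        (2.40, 3.05, 5),
        (3.70, 4.10, 5),
        (6.80, 8.40, 4),
    ]
    k = 0
    for lo, hi, n in protein_regions:
        placed = 0
        while placed < n:
            c = float(rng.uniform(lo, hi))
            if any(abs(c - p) < 0.04 for p in small_lines):
                continue
            mk(
                f"protein_{k:02d}",
                [Multiplet(c, 0.0, 1)],
                float(rng.uniform(0.72, 0.83)),
                float(rng.uniform(0.012, 0.025)),
                float(rng.uniform(60.0, 140.0)),
                float(rng.uniform(6.0, 12.0)),
            )
            placed += 1
            k += 1

    # broad lipid signals in 5.15-5.40 ppm, clear of the 5.23 anomeric
    for i, c in enumerate((5.165, 5.195, 5.30, 5.36)):
        mk(
            f"lipid_{i}",
            [Multiplet(c, 0.0, 1)],
            float(rng.uniform(0.05, 0.40)),
            float(rng.uniform(0.015, 0.025)),
            float(rng.uniform(40.0, 90.0)),
            float(rng.uniform(2.5, 4.5)),
        )

    # lipoprotein methyl/methylene, very slow diffusion
    for c in (0.84, 1.25):
        mk(
            f"lipoprotein_{c:.2f}",
            [Multiplet(c, 0.0, 1)],
            float(rng.uniform(0.04, 0.08)),
            float(rng.uniform(0.018, 0.025)),
            float(rng.uniform(50.0, 90.0)),
            float(rng.uniform(5.0, 9.0)),
        )

    return Phantom(
        name="plasma",
        species=species,
        water=_default_water(amplitude=80.0),
        reference=None,
        noise_sigma=0.05,
    )


def build_doped_water_phantom(D: float = 1.91, noise_sigma: float = 0.05) -> Phantom:
    """Single-resonance doped-water sample for gradient calibration.

    Presaturation is off (factor 1) so the water signal is dominant.
    ``D`` is the ground-truth water diffusion coefficient in
    1e-10 m^2/s.
    """
    water = Species(
        name="water",
        multiplets=(Multiplet(center_ppm=4.70, j_hz=0.0, n_lines=1),),
        D=D,
        T2=0.4,
        linewidth=2.0,
        amplitude=100.0,
        presat=1.0,
    )
    return Phantom(name="doped_water", species=[], water=water, noise_sigma=noise_sigma)


# ----------------------------------------------------------------------
# forward simulation
# ----------------------------------------------------------------------

def simulate_dataset(
    phantom: Phantom,
    params: PulseSequenceParams,
    grid: SimulationGrid = SimulationGrid(),
    seed: int = 0,
    noise_sigma: Optional[float] = None,
) -> Pseudo2DDataset:
    """Forward-simulate a time-domain pseudo-2D dataset.

    Every spectral line contributes
    ``a * exp(2j*pi*f*t - pi*linewidth*t)`` to the FID; increment ``i``
    scales each species by its attenuation at ramp amplitude ``g_i``.
    Complex Gaussian noise of sd ``noise_sigma/sqrt(n_scans)`` is added
    per increment.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ramp = seqmodel.gradient_ramp(params)
    t = np.arange(grid.points) * grid.dwell
    lo, hi = grid.ppm_bounds()
    matrix = np.zeros((params.n_increments, grid.points), dtype=np.complex128)

    for sp in phantom.all_species():
        fid = np.zeros(grid.points, dtype=np.complex128)
        r2 = np.pi * sp.linewidth  # Lorentzian FWHM -> decay rate
        for ppm, amp in sp.line_table(grid.sf_mhz):
            if not (lo <= ppm <= hi):
                raise ValueError(
                    f"line of {sp.name} at {ppm:.3f} ppm outside spectral "
                    f"width [{lo:.2f}, {hi:.2f}]"
                )
            f = (ppm - grid.carrier_ppm) * grid.sf_mhz  # Hz
            fid += amp * np.exp((2j * np.pi * f - r2) * t)
        atten = np.asarray(
            seqmodel.attenuation(params, sp.D * D_UNIT, sp.T2, ramp.amplitudes)
        )
        matrix += (sp.presat * atten)[:, None] * fid[None, :]

    sigma = phantom.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        eff = sigma / np.sqrt(params.n_scans)
        noise = rng.normal(scale=eff, size=matrix.shape) + 1j * rng.normal(
            scale=eff, size=matrix.shape
        )
        matrix = matrix + noise

    meta = {
        "params": params.to_dict(),
        "grid": grid.to_dict(),
        "domain": "time",
        "seed": seed,
        "noise_sigma": sigma,
        "phantom": phantom.name,
    }
    return Pseudo2DDataset(meta=meta, matrix=matrix, ground_truth=phantom)
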