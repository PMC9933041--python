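"""Multi-spectrum peak-list filtering and CSV export.

Loads per-spectrum peak lists (the columnar dialect written by
:mod:`dosykit.fitdosy`), keeps only peaks inside a union of
chemical-shift ranges whose fitting error is at or below a threshold and
whose intensity is at or above a floor, and exports consolidated CSV
tables plus per-range summary statistics across spectra.

Interval endpoints are inclusive on both ends.
"""

from __future__ import annotations

import math
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .fitdosy import DosyPeakList, PeakEntry

__all__ = [
    "FilterSpec",
    "ConsolidatedTable",
    "parse_ranges",
    "load_peak_lists",
    "filter_peaks",
    "summarize_range",
    "export_csv",
    "read_csv",
]

CSV_COLUMNS = ["spectrum_id", "ppm", "D_1e-10_m2s", "rel_error", "intensity"]


@dataclass(frozen=True)
class FilterSpec:
    """Selection predicate: ppm ranges (union), max fitting error,
    intensity floor."""

    ppm_ranges: tuple
    max_relative_error: float = math.inf
    min_intensity: float = 0.0

    def __post_init__(self):
        ranges = tuple((float(lo), float(hi)) for lo, hi in self.ppm_ranges)
        for lo, hi in ranges:
            if not lo < hi:
                raise ValueError(f"range low must be < high, got ({lo}, {hi})")
        if not self.max_relative_error > 0:
            raise ValueError("max_relative_error must be > 0")
        object.__setattr__(self, "ppm_ranges", ranges)

    def accepts(self, peak: PeakEntry) -> bool:
        in_range = any(lo <= peak.ppm <= hi for lo, hi in self.ppm_ranges)
        return (
            in_range
            and peak.relative_error <= self.max_relative_error
            and peak.intensity >= self.min_intensity
        )


def parse_ranges(text: str) -> tuple:
    """Parse ``"1.44:1.50,5.20:5.26"`` into ((1.44, 1.50), (5.20, 5.26))."""
    out = []
    text = text.strip()
    if not text:
        return ()
    for part in text.split(","):
        lo, hi = part.split(":")
        out.append((float(lo), float(hi)))
    return tuple(out)


@dataclass
class ConsolidatedTable:
    """Filtered rows from many spectra, sorted by (spectrum_id, ppm)."""

    rows: pd.DataFrame
    spec: Optional[FilterSpec] = None

    def __post_init__(self):
        if list(self.rows.columns) != CSV_COLUMNS:
            self.rows = self.rows.reindex(columns=CSV_COLUMNS)
        self.rows = self.rows.sort_values(
            ["spectrum_id", "ppm"], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)


def load_peak_lists(paths: Iterable) -> tuple[list[DosyPeakList], list[str]]:
    """Load one :class:`DosyPeakList` per file.

    Returns (lists, warnings); warnings carry file and line numbers for
    every malformed row.  An unparseable header raises a ``ValueError``
    naming the file.
    """
    lists: list[DosyPeakList] = []
    warnings: list[str] = []
    for path in paths:
        pl, warns = DosyPeakList.read(pathlib.Path(path))
        lists.append(pl)
        warnings.extend(warns)
    return lists, warnings


def filter_peaks(lists: Sequence[DosyPeakList], spec: FilterSpec) -> ConsolidatedTable:
    """Keep exactly the peaks accepted by ``spec`` across all spectra."""
    records = []
    for pl in lists:
        for p in pl.peaks:
            if spec.accepts(p):
                records.append(
                    {
                        "spectrum_id": pl.spectrum_id,
                        "ppm": p.ppm,
                        "D_1e-10_m2s": p.D,
                        "rel_error": p.relative_error,
                        "intensity": p.intensity,
                    }
                )
    df = pd.DataFrame.from_records(records, columns=CSV_COLUMNS)
    return ConsolidatedTable(rows=df, spec=spec)


def summarize_range(
    table: ConsolidatedTable, ppm_range: tuple[float, float]
) -> pd.DataFrame:
    """Per-spectrum (mean_D, sd_D, n) over surviving peaks in a range.

    ``sd_D`` is NaN (exported empty) when a spectrum contributes a
    single peak.
    """
    lo, hi = sorted(ppm_range)
    sub = table.rows[(table.rows.ppm >= lo) & (table.rows.ppm <= hi)]
    if sub.empty:
        return pd.DataFrame(columns=["spectrum_id", "range", "n_peaks", "mean_D", "sd_D"])
    grouped = sub.groupby("spectrum_id")["D_1e-10_m2s"]
    out = pd.DataFrame(
        {
            "spectrum_id": grouped.mean().index,
            "range": f"{lo}:{hi}",
            "n_peaks": grouped.size().values,
            "mean_D": grouped.mean().values,
            "sd_D": grouped.std(ddof=1).values,  # NaN for n=1
        }
    )
    return out.reset_index(drop=True)


def _fmt(x: float) -> str:
    return repr(float(x))


def export_csv(table: ConsolidatedTable, path) -> None:
    """Write the consolidated table as CSV (fixed header, shortest
    round-trip float formatting; byte-stable for identical inputs)."""
    path = pathlib.Path(path)
    lines = [",".join(CSV_COLUMNS)]
    for row in table.rows.itertuples(index=False):
        lines.append(
            ",".join(
                [
                    str(row.spectrum_id),
                    _fmt(row.ppm),
                    _fmt(row._2),
                    _fmt(row.rel_error),
                    _fmt(row.intensity),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def export_summary_csv(summary: pd.DataFrame, path) -> None:
    path = pathlib.Path(path)
    lines = [",".join(summary.columns)]
    for row in summary.itertuples(index=False):
        vals = []
        for col, v in zip(summary.columns, row):
            if isinstance(v, float):
                vals.append("" if math.isnan(v) else _fmt(v))
            else:
                vals.append(str(v))
        lines.append(",".join(vals))
    path.write_text("\n".join(lines) + "\n")


def read_csv(path) -> ConsolidatedTable:
    """Re-import a consolidated CSV written by :func:`export_csv`."""
    df = pd.read_csv(path, dtype={"spectrum_id": str})
    if list(df.columns) != CSV_COLUMNS:
        raise ValueError(f"{path}: unexpected CSV header {list(df.columns)}")
    return ConsolidatedTable(rows=df)
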