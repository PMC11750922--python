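"""Cell-scale calibration: morphometry constants and the area/count/length conversions.

Filament areas measured on micrographs are converted to (fractional) cell
counts by dividing by the mean projected area of one cell, and cell counts
are converted to filament lengths by multiplying with the mean axial cell
length.  The default constants come from SEM morphometry of 56 cells
(length 1.8 ± 0.4 µm, width 3.9 ± 0.7 µm, area 6.844 ± 2.194 µm²).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellMeasurement",
    "CellMorphometry",
    "DEFAULT_MORPHOMETRY",
    "measure_cells",
    "area_to_cells",
    "cells_to_length",
    "read_measurements_csv",
    "write_measurements_csv",
    "morphometry_to_json",
    "morphometry_from_json",
]


@dataclass(frozen=True)
class CellMeasurement:
    """One cell measured on an electron micrograph.

    ``length_um`` is along the filament axis, ``width_um`` across it.
    """

    length_um: float
    width_um: float

    def __post_init__(self) -> None:
        if not (self.length_um > 0):
            raise ValueError(f"cell length must be > 0, got {self.length_um}")
        if not (self.width_um > 0):
            raise ValueError(f"cell width must be > 0, got {self.width_um}")

    @property
    def area_um2(self) -> float:
        return self.length_um * self.width_um


@dataclass(frozen=True)
class CellMorphometry:
    """Summary cell morphometry used as calibration constants."""

    mean_length_um: float
    sd_length_um: float
    mean_width_um: float
    sd_width_um: float
    mean_area_um2: float
    sd_area_um2: float
    n: int

    def __post_init__(self) -> None:
        for name in ("mean_length_um", "sd_length_um", "mean_width_um",
                     "sd_width_um", "sd_area_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.mean_area_um2 > 0):
            raise ValueError("mean_area_um2 must be > 0")
        if self.n < 0:
            raise ValueError("n must be >= 0")


#: Published calibration constants (n = 56 cells measured by SEM).
#: Note the printed mean area (6.844 µm²) is NOT mean-length × mean-width
#: (7.02 µm²); it is treated as a given constant.
DEFAULT_MORPHOMETRY = CellMorphometry(
    mean_length_um=1.8,
    sd_length_um=0.4,
    mean_width_um=3.9,
    sd_width_um=0.7,
    mean_area_um2=6.844,
    sd_area_um2=2.194,
    n=56,
)


def measure_cells(measurements: Sequence[CellMeasurement]) -> CellMorphometry:
    """Summarise per-cell measurements into a :class:`CellMorphometry`.

    The mean area is the mean of the per-cell length × width products
    (E[L·W]), not the product of the means; its SD is the sample SD of
    those products.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements")
    lengths = np.array([m.length_um for m in measurements], dtype=float)
    widths = np.array([m.width_um for m in measurements], dtype=float)
    areas = lengths * widths
    ddof = 1 if len(measurements) > 1 else 0

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=ddof)) if len(x) > 1 else 0.0

    return CellMorphometry(
        mean_length_um=float(lengths.mean()),
        sd_length_um=_sd(lengths),
        mean_width_um=float(widths.mean()),
        sd_width_um=_sd(widths),
        mean_area_um2=float(areas.mean()),
        sd_area_um2=_sd(areas),
        n=len(measurements),
    )


def area_to_cells(area_um2: float, morph: CellMorphometry = DEFAULT_MORPHOMETRY) -> float:
    """Convert a filament area (µm²) to a fractional cell count.

    n_cells(t) = A_filament(t) / A_cell.  The result is deliberately not
    rounded: group means are reported at fractional precision.
    """
    if area_um2 < 0:
        raise ValueError(f"filament area must be >= 0, got {area_um2}")
    if not (morph.mean_area_um2 > 0):
        raise ValueError("mean cell area must be > 0")
    return float(area_um2) / morph.mean_area_um2


def cells_to_length(n_cells: float, morph: CellMorphometry = DEFAULT_MORPHOMETRY) -> float:
    """Convert a (fractional) cell count to filament length in µm.

    L_filament(t) = n_cells(t) × L_cell.
    """
    if n_cells < 0:
        raise ValueError(f"cell count must be >= 0, got {n_cells}")
    return float(n_cells) * morph.mean_length_um


# ---------------------------------------------------------------------------
# I/O

def read_measurements_csv(path: str | Path) -> list[CellMeasurement]:
    """Read per-cell measurements from a CSV with header cell_id,length_um,width_um."""
    df = pd.read_csv(path)
    required = {"cell_id", "length_um", "width_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return [CellMeasurement(float(r.length_um), float(r.width_um))
            for r in df.itertuples(index=False)]


def write_measurements_csv(measurements: Iterable[CellMeasurement], path: str | Path) -> None:
    rows = [{"cell_id": i, "length_um": m.length_um, "width_um": m.width_um}
            for i, m in enumerate(measurements)]
    pd.DataFrame(rows, columns=["cell_id", "length_um", "width_um"]).to_csv(path, index=False)


def morphometry_to_json(morph: CellMorphometry, path: str | Path | None = None) -> str:
    payload = asdict(morph)
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def morphometry_from_json(source: str | Path) -> CellMorphometry:
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    d = json.loads(text)
    return CellMorphometry(**d)
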