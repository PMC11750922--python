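"""Packaged reference tables: weekly increment and cell-number summaries.

``table1`` holds the mean ± SD cells added per week per size group;
``table2`` holds the mean ± SD cell number (and the corresponding
filament length) per timepoint per size group.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

__all__ = ["load_table1", "load_table2", "table2_group_means", "table2_group_sds",
           "table1_schedule_frame", "data_dir"]

_T1_COLUMNS = ["group", "day", "mean_increment", "sd_increment"]
_T2_COLUMNS = ["group", "day", "mean_cells", "sd_cells", "length_um"]


def data_dir() -> Path:
    """Directory holding the packaged fixture CSVs."""
    return Path(files("filagrow").joinpath("data"))


def _load(name: str, columns: list[str], source: str | Path | None) -> pd.DataFrame:
    path = Path(source) / name if source is not None else data_dir() / name
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[columns]


def load_table1(source: str | Path | None = None) -> pd.DataFrame:
    """Weekly increment summary (group, day, mean_increment, sd_increment)."""
    return _load("table1.csv", _T1_COLUMNS, source)


def load_table2(source: str | Path | None = None) -> pd.DataFrame:
    """Weekly cell-number summary (group, day, mean_cells, sd_cells, length_um)."""
    df = _load("table2.csv", _T2_COLUMNS, source)
    for group, sub in df.groupby("group"):
        if sub["day"].nunique() != len(sub):
            raise ValueError(f"table2: duplicate day for group {group}")
    return df


def table2_group_means(source: str | Path | None = None) -> dict[str, dict[float, float]]:
    df = load_table2(source)
    return {g: dict(zip(sub["day"].astype(float), sub["mean_cells"].astype(float)))
            for g, sub in df.groupby("group", sort=False)}


def table2_group_sds(source: str | Path | None = None) -> dict[str, dict[float, float]]:
    df = load_table2(source)
    return {g: dict(zip(sub["day"].astype(float), sub["sd_cells"].astype(float)))
            for g, sub in df.groupby("group", sort=False)}


def table1_schedule_frame(source: str | Path | None = None) -> pd.DataFrame:
    return load_table1(source)
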