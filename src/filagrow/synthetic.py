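"""Synthetic micrograph series with ground truth.

Emulates the cultivation experiment: static filaments in parallel
capillary lanes (206 µm bore), apical cell addition following a per-group
weekly increment schedule, and brightfield-like rendering with optional
blur and noise.  Ground truth (true cell counts, areas, positions) is kept
alongside so segmentation/tracking/statistics can be validated end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calibration import CellMorphometry, DEFAULT_MORPHOMETRY
from .datasets import load_table1
from .growth_stats import SIZE_GROUPS, assign_group
from .imaging import Micrograph

__all__ = [
    "GrowthSchedule",
    "FilamentSpec",
    "SyntheticScene",
    "GroundTruth",
    "NoiseParams",
    "simulate_growth",
    "render_micrograph",
    "make_paper_like_scene",
    "make_paper_like_experiment",
    "ExperimentBundle",
]

# rendering intensities
WALL_INTENSITY = 0.3
LANE_INTENSITY = 0.85
FILAMENT_INTENSITY = 0.35
TEXTURE_INTENSITY = 0.30


@dataclass(frozen=True)
class GrowthSchedule:
    """Mean ± SD cells added per (size group, interval-end day)."""

    entries: dict[tuple[str, float], tuple[float, float]]

    def __post_init__(self) -> None:
        for (g, d), (m, sd) in self.entries.items():
            if m < 0 or sd < 0:
                raise ValueError(f"schedule entry ({g}, {d}) must have mean, sd >= 0")

    @classmethod
    def default(cls) -> "GrowthSchedule":
        df = load_table1()
        return cls({(r.group, float(r.day)): (float(r.mean_increment), float(r.sd_increment))
                    for r in df.itertuples(index=False)})

    @classmethod
    def zero(cls, days: Sequence[float] = (7, 14, 21, 28)) -> "GrowthSchedule":
        return cls({(g.label, float(d)): (0.0, 0.0) for g in SIZE_GROUPS for d in days})

    def get(self, group_label: str, day: float) -> tuple[float, float]:
        try:
            return self.entries[(group_label, float(day))]
        except KeyError:
            raise KeyError(f"no schedule entry for group {group_label!r}, day {day}") from None

    def noiseless(self) -> "GrowthSchedule":
        return GrowthSchedule({k: (m, 0.0) for k, (m, _) in self.entries.items()})


@dataclass(frozen=True)
class FilamentSpec:
    """Initial placement of one filament along its lane axis."""

    filament_id: str
    lane_id: int
    center_um: float        # initial along-lane centre position
    initial_cells: int

    def __post_init__(self) -> None:
        if self.initial_cells <= 0:
            raise ValueError(f"filament {self.filament_id}: initial cells must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Imaging realism: PSF blur σ (px) and additive Gaussian noise σ."""

    sigma_psf: float = 1.0
    sigma_noise: float = 0.05
    cell_texture: bool = False  # shallow intensity dips at cross-walls

    @classmethod
    def noise_free(cls) -> "NoiseParams":
        return cls(sigma_psf=0.0, sigma_noise=0.0, cell_texture=False)


@dataclass(frozen=True)
class SyntheticScene:
    """Geometry of a simulated capillary strip experiment."""

    filaments: tuple[FilamentSpec, ...]
    timepoints: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 28.0)
    seed: int = 0
    strip_id: str = "S1"
    n_lanes: int = 10
    lane_width_um: float = 206.0
    wall_um: float = 12.0
    length_um: float = 700.0
    pixel_size: float = 0.25
    min_gap_um: float = 5.0

    def __post_init__(self) -> None:
        if self.n_lanes < 1 or self.lane_width_um <= 0 or self.length_um <= 0:
            raise ValueError("invalid lane geometry")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")
        for f in self.filaments:
            if not (0 <= f.lane_id < self.n_lanes):
                raise ValueError(f"filament {f.filament_id}: lane {f.lane_id} out of range")

    @property
    def height_um(self) -> float:
        return self.n_lanes * self.lane_width_um + (self.n_lanes + 1) * self.wall_um

    def lane_row_span_um(self, lane_id: int) -> tuple[float, float]:
        y0 = self.wall_um + lane_id * (self.lane_width_um + self.wall_um)
        return y0, y0 + self.lane_width_um

    def lane_center_um(self, lane_id: int) -> float:
        y0, y1 = self.lane_row_span_um(lane_id)
        return 0.5 * (y0 + y1)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class GroundTruthRecord:
    filament_id: str
    lane_id: int
    timepoint: float
    cells: int
    area_um2: float          # exactly cells × A_cell
    x_left_um: float
    x_right_um: float
    centroid_row_px: float
    centroid_col_px: float


@dataclass
class GroundTruth:
    """Per (filament, timepoint) true state of a simulated experiment."""

    scene: SyntheticScene
    records: list[GroundTruthRecord]

    def at(self, timepoint: float) -> list[GroundTruthRecord]:
        return [r for r in self.records if r.timepoint == timepoint]

    def cells_of(self, filament_id: str) -> dict[float, int]:
        return {r.timepoint: r.cells for r in self.records
                if r.filament_id == filament_id}

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "filament_id": r.filament_id, "lane_id": r.lane_id,
            "timepoint_days": r.timepoint, "true_cells": r.cells,
            "true_area_um2": r.area_um2, "centroid_row": r.centroid_row_px,
            "centroid_col": r.centroid_col_px,
        } for r in self.records]
        return pd.DataFrame(rows, columns=[
            "filament_id", "lane_id", "timepoint_days", "true_cells",
            "true_area_um2", "centroid_row", "centroid_col"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_growth(
    scene: SyntheticScene,
    schedule: GrowthSchedule | None = None,
    morph: CellMorphometry = DEFAULT_MORPHOMETRY,
) -> GroundTruth:
    """Simulate apical growth of every filament in the scene.

    Per interval, the cell increment is drawn Normal(mean, sd), truncated
    at 0 (growth is never negative), rounded to a whole cell, and split
    between the two tips by a fair coin per cell.  Deterministic given
    the scene seed.  Raises if any filament leaves the field or two
    filaments in a lane come closer than ``min_gap_um`` at any timepoint.
    """
    schedule = schedule or GrowthSchedule.default()
    rng = np.random.default_rng(scene.seed)
    L = morph.mean_length_um
    A = morph.mean_area_um2
    ps = scene.pixel_size

    records: list[GroundTruthRecord] = []
    for f in scene.filaments:
        group = assign_group(f.initial_cells, extend_top=True)
        if group is None:
            raise ValueError(f"filament {f.filament_id}: cannot assign size group")
        half = 0.5 * f.initial_cells * L
        x_left, x_right = f.center_um - half, f.center_um + half
        cells = f.initial_cells
        for k, t in enumerate(scene.timepoints):
            if k > 0:
                mean, sd = schedule.get(group.label, t)
                inc = int(round(max(0.0, float(rng.normal(mean, sd)))))
                left_cells = int(rng.binomial(inc, 0.5)) if inc > 0 else 0
                x_left -= left_cells * L
                x_right += (inc - left_cells) * L
                cells += inc
            records.append(GroundTruthRecord(
                filament_id=f.filament_id, lane_id=f.lane_id, timepoint=t,
                cells=cells, area_um2=cells * A,
                x_left_um=x_left, x_right_um=x_right,
                centroid_row_px=scene.lane_center_um(f.lane_id) / ps,
                centroid_col_px=0.5 * (x_left + x_right) / ps,
            ))

    _validate_layout(scene, records)
    return GroundTruth(scene=scene, records=records)


def _validate_layout(scene: SyntheticScene, records: list[GroundTruthRecord]) -> None:
    for r in records:
        if r.x_left_um < 0 or r.x_right_um > scene.length_um:
            raise ValueError(
                f"filament {r.filament_id} extends beyond the field at day {r.timepoint} "
                f"([{r.x_left_um:.1f}, {r.x_right_um:.1f}] µm vs length {scene.length_um})")
    by_lane_t: dict[tuple[int, float], list[GroundTruthRecord]] = {}
    for r in records:
        by_lane_t.setdefault((r.lane_id, r.timepoint), []).append(r)
    for (lane, t), rs in by_lane_t.items():
        rs = sorted(rs, key=lambda r: r.x_left_um)
        for a, b in zip(rs, rs[1:]):
            gap = b.x_left_um - a.x_right_um
            if gap < scene.min_gap_um:
                raise ValueError(
                    f"filaments {a.filament_id} and {b.filament_id} violate the "
                    f"{scene.min_gap_um} µm gap in lane {lane} at day {t} (gap {gap:.2f})")


def render_micrograph(
    scene: SyntheticScene,
    truth: GroundTruth,
    timepoint: float,
    noise: NoiseParams = NoiseParams(),
    morph: CellMorphometry = DEFAULT_MORPHOMETRY,
) -> Micrograph:
    """Render the strip at one timepoint.

    Each filament is drawn as a dark axis-aligned bar whose *pixel count*
    equals round(cells × A_cell / pixel_size²): the bar is cells × L_cell
    long and as wide as needed for the area to stay consistent with the
    calibration constant (any remainder pixels form a thin ridge along
    the top edge).  This keeps the area→count conversion exact on
    noise-free renders.  Blur and noise are applied afterwards;
    deterministic given the scene seed and timepoint.
    """
    ps = scene.pixel_size
    H = int(round(scene.height_um / ps))
    W = int(round(scene.length_um / ps))
    img = np.full((H, W), WALL_INTENSITY, dtype=np.float32)
    for lane in range(scene.n_lanes):
        y0, y1 = scene.lane_row_span_um(lane)
        img[int(round(y0 / ps)):int(round(y1 / ps)), :] = LANE_INTENSITY

    L = morph.mean_length_um
    A = morph.mean_area_um2
    for r in truth.at(timepoint):
        len_px = max(1, int(round(r.cells * L / ps)))
        n_px = max(1, int(round(r.area_um2 / ps ** 2)))
        w_px = max(1, n_px // len_px)
        rem = n_px - w_px * len_px
        c0 = int(round(r.x_left_um / ps))
        if c0 < 0 or c0 + len_px > W:
            raise ValueError(f"filament {r.filament_id} extends beyond the image")
        r_center = int(round(scene.lane_center_um(r.lane_id) / ps))
        r0 = r_center - w_px // 2
        lane_lo, lane_hi = scene.lane_row_span_um(r.lane_id)
        if r0 - 1 <= lane_lo / ps or r0 + w_px >= lane_hi / ps:
            raise ValueError(f"filament {r.filament_id} wider than its lane")
        img[r0:r0 + w_px, c0:c0 + len_px] = FILAMENT_INTENSITY
        if rem:
            start = c0 + (len_px - rem) // 2
            img[r0 - 1, start:start + rem] = FILAMENT_INTENSITY
        if noise.cell_texture:
            for k in range(1, r.cells):
                col = c0 + int(round(k * L / ps))
                if c0 < col < c0 + len_px:
                    img[r0:r0 + w_px, col] = TEXTURE_INTENSITY

    if noise.sigma_psf > 0:
        img = gaussian_filter(img, noise.sigma_psf)
    if noise.sigma_noise > 0:
        rng = np.random.default_rng([scene.seed, int(round(timepoint * 1000)), 0x5eed])
        img += rng.standard_normal(img.shape, dtype=np.float32) * np.float32(noise.sigma_noise)
    np.clip(img, 0.0, 1.0, out=img)
    return Micrograph(pixels=img, pixel_size=ps, timepoint=timepoint,
                      strip_id=scene.strip_id)


@dataclass
class ExperimentBundle:
    """A rendered experiment: image series, truth, and a manifest."""

    scene: SyntheticScene
    truth: GroundTruth
    images: list[Micrograph]
    manifest: pd.DataFrame


# group sampling ranges for the default 20-filament experiment
_GROUP_RANGES = {"0-50": (20, 45), "50-100": (55, 95), "100-150": (105, 145)}
_GROUP_COUNTS = {"0-50": 7, "50-100": 7, "100-150": 6}
_SLOT_CENTERS_UM = (180.0, 520.0)


def make_paper_like_scene(
    seed: int,
    pixel_size: float = 0.25,
    timepoints: Sequence[float] = (0.0, 7.0, 14.0, 21.0, 28.0),
) -> SyntheticScene:
    """Lay out the default 20-filament, 10-lane scene (no simulation).

    Initial sizes are drawn uniformly within each group's range
    (7 / 7 / 6 filaments in the small / medium / large group), two
    filaments per lane, shuffled deterministically by ``seed``.
    """
    rng = np.random.default_rng([seed, 0xF17A])
    sizes: list[int] = []
    for label in ("0-50", "50-100", "100-150"):
        lo, hi = _GROUP_RANGES[label]
        sizes.extend(int(v) for v in rng.integers(lo, hi + 1, _GROUP_COUNTS[label]))
    order = rng.permutation(len(sizes))
    filaments = []
    for slot, idx in enumerate(order):
        lane, pos = divmod(slot, len(_SLOT_CENTERS_UM))
        filaments.append(FilamentSpec(
            filament_id=f"F{idx:02d}", lane_id=lane,
            center_um=_SLOT_CENTERS_UM[pos], initial_cells=sizes[idx]))
    return SyntheticScene(filaments=tuple(filaments),
                          timepoints=tuple(float(t) for t in timepoints),
                          seed=seed, pixel_size=pixel_size)


def make_paper_like_experiment(
    seed: int,
    out_dir: str | Path | None = None,
    pixel_size: float = 0.25,
    noise: NoiseParams = NoiseParams(),
    schedule: GrowthSchedule | None = None,
    timepoints: Sequence[float] = (0.0, 7.0, 14.0, 21.0, 28.0),
    morph: CellMorphometry = DEFAULT_MORPHOMETRY,
) -> ExperimentBundle:
    """Build and render the default 20-filament experiment.

    When ``out_dir`` is given, TIFF images, ``manifest.csv``,
    ``ground_truth.csv`` and ``scene.json`` are written there.
    """
    scene = make_paper_like_scene(seed, pixel_size, timepoints)
    truth = simulate_growth(scene, schedule, morph)
    images = [render_micrograph(scene, truth, t, noise, morph) for t in scene.timepoints]

    rows = []
    for im in images:
        name = f"{scene.strip_id}_{im.timepoint:g}d.tif"
        rows.append({"path": name, "strip_id": scene.strip_id,
                     "timepoint_days": im.timepoint, "pixel_size_um": pixel_size})
    manifest = pd.DataFrame(rows, columns=["path", "strip_id", "timepoint_days", "pixel_size_um"])

    if out_dir is not None:
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for im, row in zip(images, rows):
            tifffile.imwrite(out / row["path"], im.pixels.astype(np.float32))
        manifest.assign(path=[str(out / r["path"]) for r in rows]).to_csv(
            out / "manifest.csv", index=False)
        truth.write_csv(out / "ground_truth.csv")
        scene.to_json(out / "scene.json")
    return ExperimentBundle(scene=scene, truth=truth, images=images, manifest=manifest)
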