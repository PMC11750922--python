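"""Re-identification of filaments across weekly timepoints.

Filaments inside the capillaries are essentially static, so the same
filament is recognised at the next timepoint by proximity and by the fact
that it can only have grown: matches are a per-lane optimal one-to-one
assignment on centroid distance, gated by a maximum centroid shift and a
maximum apparent shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .calibration import CellMorphometry, DEFAULT_MORPHOMETRY, area_to_cells, cells_to_length
from .imaging import FilamentObservation

__all__ = [
    "MatchingParams",
    "FilamentTrack",
    "link_timepoints",
    "build_tracks",
    "compute_increments",
]

_INFEASIBLE = 1e12


@dataclass(frozen=True)
class MatchingParams:
    """Gates for cross-timepoint matching.

    max_centroid_shift is in µm (filaments only oscillate slightly);
    max_relative_shrinkage tolerates measurement noise — true filaments
    never shrink appreciably between observations.
    """

    max_centroid_shift: float = 20.0
    max_relative_shrinkage: float = 0.1

    def __post_init__(self) -> None:
        if self.max_centroid_shift < 0 or self.max_relative_shrinkage < 0:
            raise ValueError("matching parameters must be >= 0")


@dataclass
class FilamentTrack:
    """One physical filament followed across timepoints."""

    track_id: str
    strip_id: str
    lane_id: int
    observations: dict[float, FilamentObservation] = field(default_factory=dict)
    complete: bool = True

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.observations)

    @property
    def initial_timepoint(self) -> float:
        return self.timepoints[0]

    def n_cells_series(self, morph: CellMorphometry = DEFAULT_MORPHOMETRY) -> dict[float, float]:
        return {t: area_to_cells(self.observations[t].area_um2, morph)
                for t in self.timepoints}

    def length_series(self, morph: CellMorphometry = DEFAULT_MORPHOMETRY) -> dict[float, float]:
        return {t: cells_to_length(n, morph)
                for t, n in self.n_cells_series(morph).items()}

    def initial_cells(self, morph: CellMorphometry = DEFAULT_MORPHOMETRY) -> float:
        return self.n_cells_series(morph)[self.initial_timepoint]

    @property
    def touches_edge(self) -> bool:
        return any(o.touches_roi_edge for o in self.observations.values())

    def increments(self, morph: CellMorphometry = DEFAULT_MORPHOMETRY) -> dict[tuple[float, float], float]:
        return compute_increments(self, morph)


def _centroid_um(obs: FilamentObservation) -> np.ndarray:
    return np.array(obs.centroid, dtype=float) * obs.pixel_size


def link_timepoints(
    obs_t0: Sequence[FilamentObservation],
    obs_t1: Sequence[FilamentObservation],
    params: MatchingParams = MatchingParams(),
) -> tuple[list[tuple[FilamentObservation, FilamentObservation]],
           list[FilamentObservation], list[FilamentObservation]]:
    """Match observations of one strip between two timepoints.

    Returns (matched pairs, unmatched at t0, unmatched at t1).  Within
    each lane the assignment minimises total centroid displacement,
    subject to displacement ≤ max_centroid_shift and
    area(t1) ≥ (1 − max_relative_shrinkage) × area(t0).  Ties are broken
    toward the smaller |area difference|, deterministically.
    """
    strips = {o.strip_id for o in obs_t0} | {o.strip_id for o in obs_t1}
    if len(strips) > 1:
        raise ValueError(f"observations from multiple strips: {sorted(strips)}")

    pairs: list[tuple[FilamentObservation, FilamentObservation]] = []
    un0: list[FilamentObservation] = []
    un1: list[FilamentObservation] = []

    lanes = sorted({o.lane_id for o in obs_t0} | {o.lane_id for o in obs_t1})
    for lane in lanes:
        a = sorted((o for o in obs_t0 if o.lane_id == lane),
                   key=lambda o: (o.centroid[1], o.centroid[0]))
        b = sorted((o for o in obs_t1 if o.lane_id == lane),
                   key=lambda o: (o.centroid[1], o.centroid[0]))
        if not a or not b:
            un0.extend(a)
            un1.extend(b)
            continue
        cost = np.full((len(a), len(b)), _INFEASIBLE)
        max_area = max(max(o.area_um2 for o in a), max(o.area_um2 for o in b))
        for i, oa in enumerate(a):
            for j, ob in enumerate(b):
                d = float(np.linalg.norm(_centroid_um(oa) - _centroid_um(ob)))
                if d > params.max_centroid_shift:
                    continue
                if ob.area_um2 < (1.0 - params.max_relative_shrinkage) * oa.area_um2:
                    continue
                # tiny tiebreak: prefer similar areas when distances tie
                cost[i, j] = d + 1e-9 * abs(oa.area_um2 - ob.area_um2) / max_area
        rows, cols = linear_sum_assignment(cost)
        matched0, matched1 = set(), set()
        for i, j in zip(rows, cols):
            if cost[i, j] < _INFEASIBLE / 2:
                pairs.append((a[i], b[j]))
                matched0.add(i)
                matched1.add(j)
        un0.extend(a[i] for i in range(len(a)) if i not in matched0)
        un1.extend(b[j] for j in range(len(b)) if j not in matched1)

    return pairs, un0, un1


def build_tracks(
    observations: Iterable[FilamentObservation],
    params: MatchingParams = MatchingParams(),
    morph: CellMorphometry = DEFAULT_MORPHOMETRY,
) -> list[FilamentTrack]:
    """Chain consecutive-timepoint links into tracks.

    Tracks are built per strip by linking each pair of consecutive
    timepoints; no gap closing — a filament missed at one timepoint
    terminates its track (a new track starts if it reappears).  Tracks
    not spanning every timepoint of their strip are flagged incomplete.
    """
    obs = list(observations)
    by_strip: dict[str, list[FilamentObservation]] = {}
    for o in obs:
        by_strip.setdefault(o.strip_id, []).append(o)

    tracks: list[FilamentTrack] = []
    for strip_id in sorted(by_strip):
        strip_obs = by_strip[strip_id]
        days = sorted({o.timepoint for o in strip_obs})
        if len(days) < 2:
            raise ValueError(f"strip {strip_id}: need >= 2 distinct timepoints, got {len(days)}")
        by_day = {d: [o for o in strip_obs if o.timepoint == d] for d in days}

        open_tracks: dict[int, FilamentTrack] = {}  # id(obs at latest day) -> track
        counter = 0
        for o in sorted(by_day[days[0]], key=lambda x: (x.lane_id, x.centroid[1])):
            tr = FilamentTrack(track_id=f"{strip_id}_T{counter}", strip_id=strip_id,
                               lane_id=o.lane_id, observations={o.timepoint: o})
            counter += 1
            open_tracks[id(o)] = tr
            tracks.append(tr)
        for d0, d1 in zip(days, days[1:]):
            pairs, _, un1 = link_timepoints(by_day[d0], by_day[d1], params)
            next_open: dict[int, FilamentTrack] = {}
            for oa, ob in pairs:
                tr = open_tracks.get(id(oa))
                if tr is None:
                    continue
                tr.observations[ob.timepoint] = ob
                next_open[id(ob)] = tr
            for o in sorted(un1, key=lambda x: (x.lane_id, x.centroid[1])):
                tr = FilamentTrack(track_id=f"{strip_id}_T{counter}", strip_id=strip_id,
                                   lane_id=o.lane_id, observations={o.timepoint: o})
                counter += 1
                next_open[id(o)] = tr
                tracks.append(tr)
            open_tracks = next_open
        for tr in tracks:
            if tr.strip_id == strip_id:
                tr.complete = tr.timepoints == days
    return tracks


def compute_increments(
    track: FilamentTrack,
    morph: CellMorphometry = DEFAULT_MORPHOMETRY,
) -> dict[tuple[float, float], float]:
    """Cells added per consecutive interval of a track.

    Fractional and possibly negative (measurement noise); the sum over
    all intervals equals n_cells(last) − n_cells(first) exactly.
    """
    days = track.timepoints
    if len(days) < 2:
        raise ValueError("track needs >= 2 timepoints to compute increments")
    series = track.n_cells_series(morph)
    return {(t0, t1): series[t1] - series[t0] for t0, t1 in zip(days, days[1:])}
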