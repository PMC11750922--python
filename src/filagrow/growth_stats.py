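"""Size-group growth statistics: mean curves, dN/dt slopes, increments, tests.

Filaments are binned by their initial cell number into three size groups
(0–50, 50–100, 100–150 cells).  Per group, the mean cell number per
timepoint is fitted with ordinary least squares against time; the slope is
the rate of increase of population dN/dt (cells/day), optionally
normalised by the time-mean population size.  Group differences are
assessed with one-way ANOVA and pairwise pooled-variance two-tailed
t-tests at α = 0.05.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .calibration import CellMorphometry, DEFAULT_MORPHOMETRY, cells_to_length
from .tracking import FilamentTrack

log = logging.getLogger(__name__)

__all__ = [
    "SizeGroup",
    "SIZE_GROUPS",
    "GroupGrowthSummary",
    "GroupComparison",
    "assign_group",
    "ols_slope",
    "normalized_rate",
    "summarize_groups",
    "summaries_from_group_means",
    "compare_groups",
    "hormogonia_flag",
]


@dataclass(frozen=True)
class SizeGroup:
    """A bin on initial cell number; half-open except the top bin."""

    label: str
    lo: float
    hi: float
    closed_right: bool = False

    def contains(self, n: float) -> bool:
        if self.closed_right:
            return self.lo <= n <= self.hi
        return self.lo <= n < self.hi


#: The three size groups: [0, 50), [50, 100), [100, 150].
SIZE_GROUPS = (
    SizeGroup("0-50", 0.0, 50.0),
    SizeGroup("50-100", 50.0, 100.0),
    SizeGroup("100-150", 100.0, 150.0, closed_right=True),
)


def assign_group(
    initial_cells: float,
    groups: Sequence[SizeGroup] = SIZE_GROUPS,
    extend_top: bool = False,
) -> SizeGroup | None:
    """Bin a filament by its cell number at the first timepoint.

    Returns None (ungrouped) above the top bin unless ``extend_top``.
    """
    if initial_cells < 0:
        raise ValueError("initial cell count must be >= 0")
    for g in groups:
        if g.contains(initial_cells):
            return g
    if extend_top and initial_cells > groups[-1].hi:
        return groups[-1]
    return None


def ols_slope(times: Sequence[float], values: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares of values vs times.

    Returns (slope, intercept, r_squared).  For constant values the slope
    is 0 and r² is defined as 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("need >= 2 paired (time, value) points")
    st = t - t.mean()
    sst_t = float(st @ st)
    if sst_t == 0.0:
        raise ValueError("all times identical; slope undefined")
    sy = y - y.mean()
    slope = float(st @ sy) / sst_t
    intercept = float(y.mean() - slope * t.mean())
    sst = float(sy @ sy)
    if sst == 0.0:
        return slope, intercept, 0.0
    resid = y - (intercept + slope * t)
    r2 = 1.0 - float(resid @ resid) / sst
    return slope, intercept, r2


@dataclass
class GroupGrowthSummary:
    """Per-size-group growth summary (group mean curve + linear fit)."""

    group: SizeGroup
    mean_cells_by_day: dict[float, float]
    sd_cells_by_day: dict[float, float]
    n_tracks: int
    mean_increment_by_week: dict[float, float] = field(default_factory=dict)  # keyed by end day
    sd_increment_by_week: dict[float, float] = field(default_factory=dict)
    slope: float = float("nan")        # dN/dt, cells/day
    intercept: float = float("nan")
    r_squared: float = float("nan")
    normalized_rate: float = float("nan")  # 1/day

    def lengths_by_day(self, morph: CellMorphometry = DEFAULT_MORPHOMETRY) -> dict[float, float]:
        return {d: cells_to_length(n, morph) for d, n in self.mean_cells_by_day.items()}


def normalized_rate(summary: GroupGrowthSummary) -> float:
    """dN/dt divided by the time-mean of the group's mean cell number."""
    return _normalized_rate(summary.slope, summary.mean_cells_by_day)


def _normalized_rate(slope: float, mean_cells_by_day: Mapping[float, float]) -> float:
    denom = float(np.mean(list(mean_cells_by_day.values())))
    if denom <= 0:
        raise ValueError("mean population size must be > 0 to normalise the rate")
    return slope / denom


def _fit(summary: GroupGrowthSummary) -> None:
    days = sorted(summary.mean_cells_by_day)
    ys = [summary.mean_cells_by_day[d] for d in days]
    summary.slope, summary.intercept, summary.r_squared = ols_slope(days, ys)
    summary.normalized_rate = _normalized_rate(summary.slope, summary.mean_cells_by_day)


def summarize_groups(
    tracks: Sequence[FilamentTrack],
    morph: CellMorphometry = DEFAULT_MORPHOMETRY,
    groups: Sequence[SizeGroup] = SIZE_GROUPS,
    include_incomplete: bool = False,
    include_edge_touching: bool = False,
    extend_top: bool = False,
) -> list[GroupGrowthSummary]:
    """Summarise tracks per size group.

    By default only complete tracks with no edge-touching observation
    enter the statistics (partial areas bias the cell-count conversion).
    Groups with no tracks are omitted with a warning.
    """
    usable = [tr for tr in tracks
              if (include_incomplete or tr.complete)
              and (include_edge_touching or not tr.touches_edge)]
    by_group: dict[str, list[FilamentTrack]] = {g.label: [] for g in groups}
    for tr in usable:
        g = assign_group(tr.initial_cells(morph), groups, extend_top=extend_top)
        if g is None:
            log.warning("track %s with %.1f initial cells is ungrouped; excluded",
                        tr.track_id, tr.initial_cells(morph))
            continue
        by_group[g.label].append(tr)

    out: list[GroupGrowthSummary] = []
    for g in groups:
        members = by_group[g.label]
        if not members:
            log.warning("group %s: no usable tracks; omitted", g.label)
            continue
        days = sorted({d for tr in members for d in tr.timepoints})
        cells = {tr.track_id: tr.n_cells_series(morph) for tr in members}
        mean_by_day, sd_by_day = {}, {}
        for d in days:
            vals = np.array([s[d] for s in cells.values() if d in s])
            mean_by_day[d] = float(vals.mean())
            sd_by_day[d] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        summary = GroupGrowthSummary(
            group=g, mean_cells_by_day=mean_by_day, sd_cells_by_day=sd_by_day,
            n_tracks=len(members))
        inc_by_end: dict[float, list[float]] = {}
        for tr in members:
            for (t0, t1), v in tr.increments(morph).items():
                inc_by_end.setdefault(t1, []).append(v)
        for d in sorted(inc_by_end):
            vals = np.array(inc_by_end[d])
            summary.mean_increment_by_week[d] = float(vals.mean())
            summary.sd_increment_by_week[d] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        _fit(summary)
        out.append(summary)
    return out


def summaries_from_group_means(
    mean_cells: Mapping[str, Mapping[float, float]],
    sd_cells: Mapping[str, Mapping[float, float]] | None = None,
    groups: Sequence[SizeGroup] = SIZE_GROUPS,
) -> list[GroupGrowthSummary]:
    """Build summaries directly from published per-group timepoint means.

    ``mean_cells`` maps group label → {day → mean cell number}.  Weekly
    increments are differences of consecutive means; the OLS fit runs on
    the means themselves.
    """
    by_label = {g.label: g for g in groups}
    out = []
    for label in mean_cells:
        if label not in by_label:
            raise ValueError(f"unknown group label {label!r}")
        means = {float(d): float(v) for d, v in mean_cells[label].items()}
        sds = ({float(d): float(v) for d, v in sd_cells[label].items()}
               if sd_cells and label in sd_cells else {d: 0.0 for d in means})
        s = GroupGrowthSummary(group=by_label[label], mean_cells_by_day=means,
                               sd_cells_by_day=sds, n_tracks=0)
        days = sorted(means)
        for t0, t1 in zip(days, days[1:]):
            s.mean_increment_by_week[t1] = means[t1] - means[t0]
        _fit(s)
        out.append(s)
    out.sort(key=lambda s: s.group.lo)
    return out


# ---------------------------------------------------------------------------
# Significance testing

@dataclass
class GroupComparison:
    """One-way ANOVA plus pairwise t-tests per week, with letter display."""

    anova_by_week: dict[float, tuple[float, float]]  # week/day -> (F, p)
    pairwise: dict[tuple[str, str, float], tuple[float, int, float, bool]]
    # (group_i, group_j, week) -> (t, df, p, significant at alpha)
    letters: dict[tuple[str, float], str]  # (group, week) -> letters
    alpha: float = 0.05


def _letters_for_week(labels: Sequence[str], means: Mapping[str, float],
                      sig: Mapping[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly different."""
    # non-significance graph; maximal cliques get consecutive letters
    nodes = list(labels)
    adj = {a: {b for b in nodes if b != a and not sig.get(tuple(sorted((a, b))), False)}
           for a in nodes}
    cliques: list[frozenset[str]] = []
    for r in range(len(nodes), 0, -1):
        for combo in itertools.combinations(nodes, r):
            cs = set(combo)
            if all(b in adj[a] for a, b in itertools.combinations(combo, 2)):
                if not any(cs <= c for c in cliques):
                    cliques.append(frozenset(cs))
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in nodes}
    for i, c in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in nodes:
            if g in c:
                letters[g] += ch
    return letters


def compare_groups(
    values_by_group_week: Mapping[float, Mapping[str, Sequence[float]]],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> GroupComparison:
    """Compare weekly increments across size groups.

    ``values_by_group_week`` maps week (interval-end day) → group label →
    per-filament increment values.  Per week: one-way ANOVA across the
    groups and pooled-variance two-tailed t-tests for every pair.
    """
    anova: dict[float, tuple[float, float]] = {}
    pairwise: dict[tuple[str, str, float], tuple[float, int, float, bool]] = {}
    letters: dict[tuple[str, float], str] = {}

    for week, groups in values_by_group_week.items():
        labels = list(groups)
        samples = [np.asarray(groups[g], dtype=float) for g in labels]
        if len(samples) < 2 or any(len(s) < 2 for s in samples):
            raise ValueError(f"week {week}: need >= 2 groups with >= 2 values each")
        if all(s.std(ddof=1) == 0 for s in samples):
            raise ValueError(f"week {week}: zero within-group variance in all groups; "
                             "F undefined")
        F, p = sps.f_oneway(*samples)
        anova[week] = (float(F), float(p))

        n_pairs = len(labels) * (len(labels) - 1) // 2
        sig_map: dict[tuple[str, str], bool] = {}
        for ga, gb in itertools.combinations(labels, 2):
            a, b = np.asarray(groups[ga], float), np.asarray(groups[gb], float)
            t, p2 = sps.ttest_ind(a, b, equal_var=True)
            df = len(a) + len(b) - 2
            p_eff = min(1.0, float(p2) * n_pairs) if bonferroni else float(p2)
            significant = bool(p_eff < alpha)
            key = tuple(sorted((ga, gb)))
            pairwise[(key[0], key[1], week)] = (float(t), df, p_eff, significant)
            sig_map[key] = significant
        means = {g: float(np.mean(groups[g])) for g in labels}
        for g, ltr in _letters_for_week(labels, means, sig_map).items():
            letters[(g, week)] = ltr

    return GroupComparison(anova_by_week=anova, pairwise=pairwise,
                           letters=letters, alpha=alpha)


def hormogonia_flag(
    track: FilamentTrack,
    morph: CellMorphometry = DEFAULT_MORPHOMETRY,
    threshold_cells: float = 28.0,
) -> tuple[bool, dict]:
    """Flag hormogonium-like tracks: small at start and not growing.

    A track is flagged when its initial cell count is ≤ ``threshold_cells``
    (the upper bound of the inferred growth-threshold size, 28 cells
    ≈ 50 µm) and its total increment over the experiment — negative weekly
    increments clipped to 0, growth cannot be biologically negative — is
    below one cell.
    """
    initial = track.initial_cells(morph)
    if len(track.timepoints) >= 2:
        clipped_total = sum(max(0.0, v) for v in track.increments(morph).values())
    else:
        clipped_total = 0.0
    flagged = initial <= threshold_cells and clipped_total < 1.0
    report = {
        "track_id": track.track_id,
        "initial_cells": initial,
        "threshold_cells": threshold_cells,
        "total_clipped_increment": clipped_total,
        "hormogonium_like": flagged,
    }
    return flagged, report
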