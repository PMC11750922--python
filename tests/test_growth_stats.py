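import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import filagrow as fg
from filagrow.datasets import table2_group_means, table2_group_sds
from filagrow.growth_stats import (SIZE_GROUPS, assign_group, compare_groups,
                                   hormogonia_flag, normalized_rate, ols_slope,
                                   summaries_from_group_means, summarize_groups)
from tests.conftest import make_obs
from tests.test_tracking import track_from_series

DAYS = [0.0, 7.0, 14.0, 21.0, 28.0]


class TestAssignGroup:
    @pytest.mark.parametrize("n,label", [
        (27.7, "0-50"), (0.0, "0-50"), (49.99, "0-50"),
        (50.0, "50-100"), (99.99, "50-100"),
        (100.0, "100-150"), (150.0, "100-150"),
    ])
    def test_bins(self, n, label):
        assert assign_group(n).label == label

    def test_above_top_is_ungrouped(self):
        assert assign_group(160.0) is None
        assert assign_group(160.0, extend_top=True).label == "100-150"

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            assign_group(-1.0)


class TestOlsSlope:
    def test_medium_group_slope(self):
        slope, intercept, r2 = ols_slope(DAYS, [69.3, 72.7, 76.2, 77.8, 83.1])
        assert slope == pytest.approx(0.467, abs=5e-4)
        assert 0.9 < r2 <= 1.0

    def test_constant_values(self):
        slope, intercept, r2 = ols_slope([0, 7, 14], [5.0, 5.0, 5.0])
        assert slope == 0.0
        assert intercept == 5.0
        assert r2 == 0.0

    def test_two_points(self):
        slope, intercept, _ = ols_slope([0, 28], [0, 28])
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0)

    def test_all_times_equal_raises(self):
        with pytest.raises(ValueError):
            ols_slope([7, 7, 7], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_sse_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 30, rng.integers(3, 9)))
        y = rng.normal(50, 10, len(t))

        def sse_of_slope(s):
            # intercept profiled out at its optimum for this slope
            b = np.mean(y - s * t)
            return float(np.sum((y - s * t - b) ** 2))

        res = minimize_scalar(sse_of_slope, bounds=(-50, 50), method="bounded",
                              options={"xatol": 1e-10})
        slope, _, _ = ols_slope(t, y)
        assert slope == pytest.approx(res.x, abs=1e-6)


class TestNormalizedRate:
    def test_zero_slope(self):
        s = summaries_from_group_means({"0-50": dict(zip(DAYS, [10] * 5))})[0]
        assert s.slope == 0.0
        assert normalized_rate(s) == 0.0

    def test_medium_group_value(self):
        means = table2_group_means()
        s = summaries_from_group_means({"50-100": means["50-100"]})[0]
        assert normalized_rate(s) == pytest.approx(0.467 / 75.82, rel=2e-3)

    def test_maximal_for_middle_group(self):
        summaries = summaries_from_group_means(table2_group_means())
        rates = {s.group.label: normalized_rate(s) for s in summaries}
        assert max(rates, key=rates.get) == "50-100"


class TestFixtureSlopes:
    def test_three_printed_slopes(self):
        summaries = summaries_from_group_means(table2_group_means(),
                                               table2_group_sds())
        slopes = {s.group.label: round(s.slope, 2) for s in summaries}
        assert slopes == {"0-50": 0.09, "50-100": 0.47, "100-150": 0.39}

    def test_monotone_group_ordering(self):
        summaries = summaries_from_group_means(table2_group_means())
        s = {x.group.label: x.slope for x in summaries}
        assert s["0-50"] < s["100-150"] < s["50-100"]


class TestSummarizeGroups:
    def test_single_flat_track(self, morph):
        tr = track_from_series(dict.fromkeys(DAYS, 30.0), morph)
        (s,) = summarize_groups([tr], morph)
        assert s.group.label == "0-50"
        assert s.slope == 0.0
        assert all(v == 0.0 for v in s.sd_cells_by_day.values())

    def test_simulated_schedule_recovered_exactly(self, morph, truth_obs):
        # noiseless simulation -> perfect observations -> group summary
        # increments equal the simulated ones at 1-decimal precision
        bundle = fg.make_paper_like_experiment(
            seed=5, pixel_size=0.5, noise=fg.NoiseParams.noise_free())
        truth = bundle.truth
        tracks = fg.build_tracks(truth_obs(truth), morph=morph)
        summaries = summarize_groups(tracks, morph)
        assert {s.group.label for s in summaries} == {g.label for g in SIZE_GROUPS}
        # oracle: group-mean increments computed directly from true counts
        for s in summaries:
            members = [f for f in bundle.scene.filaments
                       if assign_group(f.initial_cells).label == s.group.label]
            for d0, d1 in zip(DAYS, DAYS[1:]):
                true_incs = [truth.cells_of(f.filament_id)[d1]
                             - truth.cells_of(f.filament_id)[d0] for f in members]
                assert round(s.mean_increment_by_week[d1], 1) == \
                    round(float(np.mean(true_incs)), 1)

    def test_edge_touching_tracks_excluded(self, morph):
        tr = track_from_series({0: 30.0, 7: 31.0}, morph)
        edge = track_from_series({0: 32.0, 7: 33.0}, morph)
        for d in edge.timepoints:
            o = edge.observations[d]
            edge.observations[d] = make_obs(day=d, area=o.area_um2,
                                            centroid=o.centroid, touches=True)
        (s,) = summarize_groups([tr, edge], morph)
        assert s.n_tracks == 1

    def test_empty_input_no_groups(self, morph):
        assert summarize_groups([], morph) == []


class TestCompareGroups:
    def test_identical_groups_f_zero(self):
        data = {7.0: {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}}
        cmp = compare_groups(data)
        F, p = cmp.anova_by_week[7.0]
        assert F == pytest.approx(0.0, abs=1e-12)
        assert not any(sig for (_, _, _, sig) in cmp.pairwise.values())

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        data = {7.0: {"lo": list(rng.normal(0, 0.01, 5)),
                      "hi": list(rng.normal(10, 0.01, 5))}}
        cmp = compare_groups(data)
        (_, _, p, sig) = cmp.pairwise[("hi", "lo", 7.0)]
        assert sig and p < 0.05

    def test_hand_computed_t_test(self):
        # pooled SD = 1, t = -3/sqrt(2/3) = -3.674, df = 4, p ~ 0.0213
        cmp = compare_groups({7.0: {"a": [1, 2, 3], "b": [4, 5, 6]}})
        t, df, p, sig = cmp.pairwise[("a", "b", 7.0)]
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=5e-4)
        assert sig

    def test_zero_variance_everywhere_raises(self):
        with pytest.raises(ValueError, match="variance"):
            compare_groups({7.0: {"a": [1.0, 1.0], "b": [2.0, 2.0]}})

    def test_permutation_invariance(self):
        data = {7.0: {"a": [1.0, 2.0, 3.0, 4.0], "b": [4.0, 5.0, 6.0, 2.0]}}
        ref = compare_groups(data)
        shuffled = {7.0: {"a": [3.0, 1.0, 4.0, 2.0], "b": [2.0, 6.0, 5.0, 4.0]}}
        got = compare_groups(shuffled)
        assert got.anova_by_week == ref.anova_by_week
        assert got.pairwise == ref.pairwise

    def test_letters_partition(self):
        rng = np.random.default_rng(1)
        data = {7.0: {
            "low": list(rng.normal(0.30, 0.2, 7)),
            "mid": list(rng.normal(0.33, 0.2, 7)),
            "high": list(rng.normal(8.0, 0.5, 7)),
        }}
        cmp = compare_groups(data)
        letters = {g: cmp.letters[(g, 7.0)] for g in ("low", "mid", "high")}
        # high differs from both; low and mid share a letter
        assert set(letters["low"]) & set(letters["mid"])
        assert not set(letters["high"]) & set(letters["low"])
        assert not set(letters["high"]) & set(letters["mid"])

    def test_bonferroni_weakens(self):
        data = {7.0: {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0],
                      "c": [1.5, 2.5, 3.5]}}
        plain = compare_groups(data)
        bonf = compare_groups(data, bonferroni=True)
        p_plain = plain.pairwise[("a", "b", 7.0)][2]
        p_bonf = bonf.pairwise[("a", "b", 7.0)][2]
        assert p_bonf == pytest.approx(min(1.0, 3 * p_plain))


class TestHormogonia:
    def test_small_static_flagged(self, morph):
        tr = track_from_series({0: 6.0, 7: 6.0, 14: 6.0}, morph)
        flagged, report = hormogonia_flag(tr, morph)
        assert flagged
        assert report["total_clipped_increment"] == pytest.approx(0.0, abs=1e-9)

    def test_large_never_flagged(self, morph):
        tr = track_from_series({0: 111.6, 7: 111.6}, morph)
        assert not hormogonia_flag(tr, morph)[0]

    def test_growing_small_not_flagged(self, morph):
        tr = track_from_series({0: 27.7, 7: 29.95}, morph)  # +2.25 cells
        assert not hormogonia_flag(tr, morph)[0]

    def test_negative_increments_clipped(self, morph):
        tr = track_from_series({0: 20.0, 7: 19.0, 14: 19.5}, morph)
        flagged, report = hormogonia_flag(tr, morph)
        assert flagged
        assert report["total_clipped_increment"] == pytest.approx(0.5, abs=1e-9)


class TestParameterRecovery:
    def test_mean_fitted_slope_within_10pct_of_schedule(self):
        # 100 seeded simulations at the packaged increment schedule;
        # reference slope is the fit to the noiseless mean schedule
        schedule = fg.GrowthSchedule.default()
        reference = {}
        for g in ("0-50", "50-100", "100-150"):
            cum = [0.0]
            for d in DAYS[1:]:
                cum.append(cum[-1] + schedule.get(g, d)[0])
            reference[g] = ols_slope(DAYS, cum)[0]

        fitted = {g: [] for g in reference}
        for seed in range(100):
            bundle_scene = fg.make_paper_like_experiment(
                seed=seed, pixel_size=0.5, noise=fg.NoiseParams.noise_free(),
                timepoints=DAYS).scene
            truth = fg.simulate_growth(bundle_scene, schedule)
            per_group = {g: [] for g in reference}
            for f in bundle_scene.filaments:
                g = assign_group(f.initial_cells).label
                counts = truth.cells_of(f.filament_id)
                per_group[g].append([counts[d] for d in DAYS])
            for g, rows in per_group.items():
                means = np.mean(rows, axis=0)
                fitted[g].append(ols_slope(DAYS, means)[0])
        for g in reference:
            mean_slope = float(np.mean(fitted[g]))
            assert abs(mean_slope - reference[g]) <= 0.10 * reference[g]
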