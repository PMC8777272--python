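"""Response scoring, the responsiveness rule and the pattern census."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fouriermotion as fm
from fouriermotion.census import MOVING_CONDITIONS, pattern_label, _ranksum_p


@pytest.fixture
def index(small_protocol):
    return fm.build_epoch_index(small_protocol)


class TestEpochIndex:
    def test_eight_seconds_static_is_31_frames(self):
        proto = fm.build_protocol(
            reps_per_direction=1, conditions=["square"], directions=["left"], seed=0
        )
        index = fm.build_epoch_index(proto, 3.91)
        (span,) = index.static("square:left")
        assert span[1] - span[0] == 31  # floor(8 x 3.91)

    def test_spans_tile_without_overlap(self, index):
        spans = [index.black] + [
            s for key in index.spans.values() for s in key
        ]
        spans.sort()
        for (a0, b0), (a1, b1) in zip(spans[:-1], spans[1:]):
            assert b0 <= a1
        assert spans[0][0] == 0

    def test_repetition_counts_recovered(self):
        proto = fm.build_protocol(reps_per_direction=20, seed=5)
        index = fm.build_epoch_index(proto)
        for cond in MOVING_CONDITIONS:
            assert len(index.moving(cond)) == 20
            assert len(index.static(cond)) == 20

    def test_frame_count_mismatch_rejected(self, small_protocol):
        with pytest.raises(ValueError, match="frames"):
            fm.build_epoch_index(small_protocol, n_frames=100)


class TestScoreResponses:
    def test_hand_computed_population_z(self, index):
        # 3 ROIs with deltas {1, 2, 3}: z = (d - 2) / std([1,2,3])
        n = index.n_frames
        activity = np.zeros((n, 3))
        for i, level in enumerate((1.0, 2.0, 3.0)):
            for a, b in index.moving("square:left"):
                activity[a:b, i] = level
        scores = fm.score_responses(activity, index, conditions=["square:left"])
        z = scores.sort_values("roi")["z"].to_numpy()
        np.testing.assert_allclose(z, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_roi_at_population_mean_has_zero_z(self, index):
        n = index.n_frames
        activity = np.zeros((n, 3))
        for a, b in index.moving("square:left"):
            activity[a:b] = [0.0, 0.5, 1.0]
        scores = fm.score_responses(activity, index, conditions=["square:left"])
        assert scores.sort_values("roi")["z"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_silent_roi_has_zero_delta(self, index):
        activity = np.zeros((index.n_frames, 2))
        activity[:, 1] = 0.3  # constant everywhere: delta also 0
        scores = fm.score_responses(activity, index, conditions=["square:left"])
        np.testing.assert_allclose(scores["delta"], 0.0, atol=1e-12)

    def test_z_below_minus_one_marks_ineligible(self, index):
        n = index.n_frames
        activity = np.zeros((n, 4))
        for a, b in index.moving("square:left"):
            activity[a:b] = [0.0, 1.0, 1.0, 1.0]  # first ROI far below mean
        scores = fm.score_responses(activity, index, conditions=["square:left"])
        eligible = scores.sort_values("roi")["eligible"].to_numpy()
        assert list(eligible) == [False, True, True, True]


class TestIsResponsive:
    def spans(self, n_reps, length=46, gap=100):
        return [(k * (length + gap), k * (length + gap) + length) for k in range(n_reps)]

    def sig_with(self, spans, n_frames_active, reps_active, total):
        sig = np.zeros(total, dtype=bool)
        for a, _ in spans[:reps_active]:
            sig[a : a + n_frames_active] = True
        return sig

    def test_boundary_4_frames_in_half_of_reps(self):
        spans = self.spans(20)
        total = spans[-1][1] + 10
        assert fm.is_responsive(self.sig_with(spans, 4, 10, total), spans)

    def test_below_half_of_reps_not_responsive(self):
        spans = self.spans(20)
        total = spans[-1][1] + 10
        assert not fm.is_responsive(self.sig_with(spans, 4, 9, total), spans)

    def test_three_frames_everywhere_not_responsive(self):
        spans = self.spans(20)
        total = spans[-1][1] + 10
        assert not fm.is_responsive(self.sig_with(spans, 3, 20, total), spans)


class TestProfiles:
    def test_pattern_space_is_2_to_the_k(self):
        for k, expected in ((6, 64), (4, 16)):
            conds = MOVING_CONDITIONS[:k]
            patterns = {
                int(np.dot(bits, 1 << np.arange(k)))
                for bits in itertools.product([0, 1], repeat=k)
            }
            assert len(patterns) == expected
            rows = np.array(list(itertools.product([0, 1], repeat=k)))
            df = fm.profile_neurons(rows, conds)
            assert df["pattern"].nunique() == expected

    def test_left_right_relabeling_permutes_profiles(self, rng):
        resp = rng.random((50, 6)) < 0.3
        df = fm.profile_neurons(resp)
        swapped = resp[:, [1, 0, 3, 2, 5, 4]]  # swap L and R within conditions
        df_swapped = fm.profile_neurons(swapped)
        for orig, new in zip(df["pattern"], df_swapped["pattern"]):
            bits = [(orig >> b) & 1 for b in range(6)]
            expect = sum(
                bit << pos
                for bit, pos in zip(bits, [1, 0, 3, 2, 5, 4])
            )
            assert new == expect

    def test_all_zero_pattern_is_non_responder(self):
        df = fm.profile_neurons(np.zeros((3, 6), dtype=bool))
        assert not df["responder"].any()
        assert (df["label"] == "none").all()

    def test_behavioral_output_pattern_label(self):
        # square-left + missing-fundamental-right + third-harmonic-right
        pattern = 1 + 8 + 32
        assert pattern_label(pattern) == "SqL+MFR+3hR"


class TestSplitStaticMoving:
    def fill(self, sig, spans):
        for a, b in spans:
            sig[a:b] = True

    def test_three_way_split(self, index):
        n = index.n_frames
        sig = np.zeros((n, 3), dtype=bool)
        self.fill(sig[:, 0], index.static("square:left"))
        self.fill(sig[:, 1], index.moving("square:left"))
        self.fill(sig[:, 2], index.static("square:left"))
        self.fill(sig[:, 2], index.moving("square:left"))
        labels = fm.split_static_moving(sig, index, "square:left")
        assert list(labels) == ["static_only", "moving_only", "both"]


class TestCensusCompare:
    def make_profiles(self, pcts_by_region, n_per_larva=1000):
        """pcts_by_region: region -> larva -> {pattern: count}."""
        rows = []
        for region, larvae in pcts_by_region.items():
            for larva, patterns in larvae.items():
                n_resp = sum(patterns.values())
                for pattern, count in patterns.items():
                    rows += [
                        {"larva": larva, "region": region, "pattern": pattern}
                    ] * count
                rows += [
                    {"larva": larva, "region": region, "pattern": 0}
                ] * (n_per_larva - n_resp)
        return pd.DataFrame(rows)

    def test_identical_regions_give_p_1(self):
        larvae = {f"l{i}": {1: 10} for i in range(3)}
        profiles = self.make_profiles(
            {"tectum": larvae, "pretectum": {f"m{i}": {1: 10} for i in range(3)}}
        )
        out = fm.census_compare(profiles)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_wilcoxon_exact_p_matches_rank_enumeration(self):
        # {1,2,3} vs {4,5,6} per-larva percentages -> exact p = 2/20 = 0.1
        profiles = self.make_profiles(
            {
                "tectum": {f"l{i}": {1: c} for i, c in enumerate((10, 20, 30))},
                "pretectum": {f"m{i}": {1: c} for i, c in enumerate((40, 50, 60))},
            }
        )
        out = fm.census_compare(profiles)
        assert out.loc[0, "p"] == pytest.approx(0.1, abs=1e-12)
        # brute force: all C(6,3)=20 rank assignments
        combined = [1, 2, 3, 4, 5, 6]
        observed = sum(combined[:3])
        sums = [sum(c) for c in itertools.combinations(combined, 3)]
        extreme = sum(
            1 for s in sums if abs(s - 10.5) >= abs(observed - 10.5)
        )
        assert extreme / len(sums) == pytest.approx(0.1)

    def test_benjamini_hochberg_step_up_hand_values(self):
        from statsmodels.stats.multitest import multipletests

        _, q, *_ = multipletests([0.01, 0.02, 0.04, 0.5], method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.0533, 0.5], atol=1e-4)

    def test_floor_drops_rare_patterns(self):
        profiles = self.make_profiles(
            {
                "tectum": {"l0": {1: 20, 2: 1}, "l1": {1: 20}},
                "pretectum": {"m0": {1: 20}, "m1": {1: 20}},
            },
            n_per_larva=2000,
        )
        out = fm.census_compare(profiles, floor_pct=0.1)
        # pattern 2: 1/4000 pooled = 0.025% in tectum -> below the floor
        assert set(out["pattern"]) == {1}

    def test_single_larva_region_skips_comparison(self):
        profiles = self.make_profiles(
            {
                "tectum": {"l0": {1: 20}},
                "pretectum": {"m0": {1: 20}, "m1": {1: 20}},
            }
        )
        with pytest.warns(UserWarning, match="fewer than 2 larvae"):
            out = fm.census_compare(profiles)
        assert np.isnan(out.loc[0, "p"])
        assert out.loc[0, "pct_tectum"] > 0

    def test_census_percentages_account_for_every_neuron(self, rng):
        patterns = rng.integers(0, 64, 500)
        profiles = pd.DataFrame(
            {"larva": "l0", "region": "tectum", "pattern": patterns}
        )
        out = fm.census_compare(profiles, floor_pct=0.0)
        responder_pct = out["pct_tectum"].sum()
        nonresponder_pct = 100.0 * (patterns == 0).mean()
        assert responder_pct + nonresponder_pct == pytest.approx(100.0)

    def test_exact_vs_asymptotic_switch(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert _ranksum_p(a, b) == pytest.approx(float(expected.pvalue))


class TestSpatialReport:
    def test_hemisphere_percentages_sum_to_100(self, rng):
        profiles = pd.DataFrame({"pattern": rng.integers(1, 5, 200)})
        quadrants = pd.DataFrame(
            {
                "hemisphere": rng.choice(["left", "right"], 200),
                "axis": rng.choice(["rostral", "caudal"], 200),
            }
        )
        out = fm.spatial_report(profiles, quadrants)
        np.testing.assert_allclose(out["pct_left"] + out["pct_right"], 100.0)
        np.testing.assert_allclose(out["pct_caudal"] + out["pct_rostral"], 100.0)

    def test_planted_lateralization_recovered(self, rng):
        n = 400
        caudal = rng.random(n) < 0.8
        profiles = pd.DataFrame({"pattern": np.ones(n, dtype=int)})
        quadrants = pd.DataFrame(
            {
                "hemisphere": rng.choice(["left", "right"], n),
                "axis": np.where(caudal, "caudal", "rostral"),
            }
        )
        out = fm.spatial_report(profiles, quadrants)
        ci = 3 * 100 * np.sqrt(0.8 * 0.2 / n)
        assert abs(out.loc[0, "pct_caudal"] - 80.0) < ci

    def test_empty_groups_omitted(self):
        profiles = pd.DataFrame({"pattern": [1, 1, 3]})
        quadrants = pd.DataFrame({"hemisphere": ["left", "right", "left"]})
        out = fm.spatial_report(profiles, quadrants, patterns=[1, 2, 3])
        assert list(out["pattern"]) == [1, 3]
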