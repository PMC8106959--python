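"""Screen statistics: toxicity, rescue index, hits, gated comparisons, power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from capscreen import (exclude_toxic, rescue_index, call_hits, analyze_screen,
                       percent_of_control, compare_groups, posthoc_power,
                       screen_summary, generate_screen, ScreenDesign)
from capscreen.stats import _dunn


def _records(rows):
    return pd.DataFrame(rows, columns=["plate", "well", "embryo_id",
                                       "compound_id", "toxicity", "n_scored",
                                       "n_crossed"])


class TestExcludeToxic:
    def _screen_records(self, toxic_states):
        rows = []
        for i, state in enumerate(toxic_states):
            rows.append([1, "A1", f"e{i}", f"C{i:04d}", state, 8, 2])
        return _records(rows)

    def test_partition_is_conserved(self):
        rng = np.random.default_rng(0)
        states = rng.choice(["none", "death", "delayed", "malformed"], 200)
        recs = self._screen_records(states)
        kept, summary = exclude_toxic(recs)
        assert len(kept) + summary["n_excluded"] == summary["n_total"]

    def test_no_toxic_records(self):
        kept, summary = exclude_toxic(self._screen_records(["none"] * 10))
        assert summary["n_excluded"] == 0
        assert summary["percent_excluded"] == 0.0
        assert len(kept) == 10


class TestRescueIndex:
    def test_worked_example_five_of_eight_vs_two_of_eight(self):
        assert rescue_index([(5, 8)], [(2, 8)]) == pytest.approx(2.5)

    def test_self_normalization(self):
        g = [(3, 8), (2, 8), (4, 8)]
        assert rescue_index(g, g) == pytest.approx(1.0)

    def test_pooled_counts_hand_example(self):
        treated = [(3, 8), (5, 8), (4, 8)]
        control = [(2, 8), (2, 8), (2, 8)]
        assert rescue_index(treated, control) == pytest.approx(2.0)

    def test_per_embryo_mode(self):
        treated = [(4, 8), (8, 8)]       # fractions 0.5, 1.0 -> mean 0.75
        control = [(2, 8), (2, 8)]
        assert rescue_index(treated, control, method="per-embryo") == \
            pytest.approx(0.75 / 0.25)

    def test_zero_control_crossings_is_undefined_not_infinite(self):
        with pytest.warns(UserWarning):
            ri = rescue_index([(5, 8)], [(0, 8)])
        assert math.isnan(ri)

    @given(st.integers(1, 50))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, factor):
        treated = [(3, 8), (5, 8)]
        control = [(2, 8), (1, 8)]
        scaled_t = [(c * factor, s * factor) for c, s in treated]
        scaled_c = [(c * factor, s * factor) for c, s in control]
        assert rescue_index(scaled_t, scaled_c) == \
            pytest.approx(rescue_index(treated, control))


class TestCallHits:
    def test_threshold_is_inclusive(self):
        res = pd.DataFrame(dict(compound_id=["a", "b"],
                                rescue_index=[2.5, 2.49],
                                excluded_reason=["", ""]))
        out = call_hits(res)
        assert out.hit.tolist() == [True, False]

    def test_monotone_in_rescue_index(self):
        ris = np.linspace(0, 5, 21)
        res = pd.DataFrame(dict(compound_id=[f"c{i}" for i in range(21)],
                                rescue_index=ris, excluded_reason=""))
        hits = call_hits(res).hit.to_numpy()
        assert (np.diff(hits.astype(int)) >= 0).all()

    def test_excluded_compounds_are_never_hits(self):
        res = pd.DataFrame(dict(compound_id=["a"], rescue_index=[9.0],
                                excluded_reason=["toxic:death"]))
        assert not call_hits(res).hit.any()


class TestScreenRecovery:
    def test_strong_actives_recovered_from_simulated_screen(self):
        design = ScreenDesign.replicate_study(seed=5)
        records, _ = generate_screen(design)
        results = analyze_screen(records)
        true_active = {f"C{i + 1:04d}" for i, k in enumerate(design.classes)
                       if k.kind == "active"}
        hits = set(results[results.hit].compound_id)
        assert len(hits & true_active) >= 11
        # hit-rate arithmetic of the summary
        summary = screen_summary(results)
        assert summary["first_stage_hit_rate_pct"] == \
            pytest.approx(100.0 * len(hits) / 982)

    def test_all_inactive_screen_false_positive_rate(self):
        # binomial null: P(RI >= 2.5) for an inactive compound is tiny
        design = ScreenDesign(n_compounds=200, seed=21)
        records, _ = generate_screen(design)
        results = analyze_screen(records)
        assert results.hit.sum() <= 2


class TestPercentOfControl:
    def test_identical_groups_are_100_percent(self):
        g = [30.0, 35.0, 40.0]
        assert percent_of_control(g, g) == pytest.approx(100.0)

    def test_reported_length_ratio_arithmetic(self):
        assert percent_of_control([47.33], [35.06]) == \
            pytest.approx(135.0, abs=0.05)

    def test_zero_control_mean_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(percent_of_control([1.0], [0.0]))

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            percent_of_control([], [1.0])


class TestCompareGroups:
    def test_normal_samples_take_the_parametric_branch(self):
        rng = np.random.default_rng(1)
        rep = compare_groups([rng.normal(0, 1, 50), rng.normal(0.7, 1, 50)])
        assert rep.parametric and rep.test == "t-test"

    def test_lognormal_samples_take_the_rank_branch(self):
        rng = np.random.default_rng(2)
        rep = compare_groups([rng.lognormal(0, 1, 50),
                              rng.lognormal(0.7, 1, 50)])
        assert not rep.parametric and rep.test == "Mann-Whitney U"

    def test_three_group_posthoc_choices(self):
        rng = np.random.default_rng(0)
        normal = [rng.normal(0, 1, 30), rng.normal(1, 1, 30),
                  rng.normal(0.5, 1, 30)]
        assert compare_groups(normal, "vs-control").test == \
            "one-way ANOVA + Dunnett"
        assert compare_groups(normal, "all-pairs").test == \
            "one-way ANOVA + Tukey"
        skewed = [rng.lognormal(0, 1, 30) for _ in range(3)]
        rep = compare_groups(skewed, "all-pairs")
        assert rep.test == "Kruskal-Wallis + Dunn"
        assert len(rep.posthoc) == 3

    def test_textbook_two_group_example_to_1e6(self):
        # pooled-variance t on [1,2,3] vs [2,3,4]: t = -1/sqrt(2/3), df = 4
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        t_exact = -1.0 / math.sqrt(2.0 / 3.0)
        p_exact = 2.0 * sps.t.sf(abs(t_exact), df=4)
        rep = compare_groups([a, b])
        assert rep.statistic == pytest.approx(t_exact, abs=1e-9)
        assert rep.p_value == pytest.approx(p_exact, abs=1e-6)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([[1.0, 2.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            compare_groups([[1.0, 2.0, 3.0]])

    def test_dunn_hand_computed_example(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]),
                  np.array([7.0, 8.0, 9.0])]
        out = _dunn(groups, [(0, 1), (0, 2), (1, 2)])
        # mean ranks 2, 5, 8; se = sqrt(7.5 * 2/3); 3 comparisons
        se = math.sqrt(7.5 * 2.0 / 3.0)
        z01 = -3.0 / se
        p01 = min(1.0, 3 * 2 * sps.norm.sf(abs(z01)))
        assert out[0]["statistic"] == pytest.approx(z01)
        assert out[0]["p_value"] == pytest.approx(p01)


class TestPosthocPower:
    def test_null_effect_power_equals_alpha(self):
        assert posthoc_power([1.0, 1.0], [1.0, 1.0], [30, 30],
                             alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_power_matches_monte_carlo_of_the_t_test(self):
        rng = np.random.default_rng(7)
        n, d, reps = 30, 1.0, 50_000
        x = rng.normal(0.0, 1.0, (reps, n))
        y = rng.normal(d, 1.0, (reps, n))
        p = sps.ttest_ind(x, y, axis=1).pvalue
        mc = float((p < 0.05).mean())
        assert posthoc_power([0.0, d], [1.0, 1.0], [n, n]) == \
            pytest.approx(mc, abs=0.01)

    def test_power_monotone_in_n_and_effect(self):
        p_small = posthoc_power([0.0, 0.5], [1.0, 1.0], [10, 10])
        p_more_n = posthoc_power([0.0, 0.5], [1.0, 1.0], [40, 40])
        p_more_d = posthoc_power([0.0, 1.0], [1.0, 1.0], [10, 10])
        assert p_more_n > p_small and p_more_d > p_small

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(posthoc_power([1.0, 2.0], [0.0, 0.0], [5, 5]))
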