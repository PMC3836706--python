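"""Choice curves, phenotype classification, framing tests, exclusions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import dreadchoice as dc
from dreadchoice.behavior import BIN_ORDER, ChoiceCurve


def curve_from_counts(later, total, experiment=1):
    return ChoiceCurve(
        n_later=dict(zip(BIN_ORDER, later)),
        n_total=dict(zip(BIN_ORDER, total)),
        experiment=experiment)


def fisher_oracle(k1, n1, k2, n2):
    """Independent two-sided Fisher p by hypergeometric enumeration."""
    M, n, N = n1 + n2, k1 + k2, n1
    rv = stats.hypergeom(M, n, N)
    p_obs = rv.pmf(k1)
    support = np.arange(max(0, n - n2), min(n, n1) + 1)
    return float(np.sum(rv.pmf(support)[rv.pmf(support) <= p_obs * (1 + 1e-9)]))


class TestChoiceCurve:
    def test_all_later_choices(self, exp1_design):
        data = dc.ChoiceDataset.from_pairs("s", "pain", exp1_design,
                                           [1] * len(exp1_design))
        curve = dc.choice_curve(data)
        for b in curve.populated_bins:
            assert curve.proportions[b] == 1.0

    def test_random_chooser_near_half_everywhere(self):
        cfg = dc.DesignConfig(n_choice_trials=2500, n_zero_delay_pairs=250)
        pairs = dc.generate_exp1_choice_set(cfg, seed=3)
        agent = dc.AgentSpec(spec=dc.ModelSpec("null"),
                             params=dc.ModelParams(beta=0.0))
        data = dc.simulate_agent(pairs, agent, seed=4)
        curve = dc.choice_curve(data)
        for b in curve.populated_bins:
            n = curve.n_total[b]
            sd = 0.5 / np.sqrt(n)
            assert abs(curve.proportions[b] - 0.5) < 3 * sd

    def test_strong_dreader_shows_negative_preference(self):
        """An undiscounted-dread agent expedites pain: later-choice
        proportion starts at the 0.5 bound and falls across delay bins."""
        cfg = dc.DesignConfig(n_choice_trials=1000, n_zero_delay_pairs=100)
        pairs = dc.generate_exp1_choice_set(cfg, seed=5)
        agent = dc.AgentSpec(
            spec=dc.ModelSpec("undiscounted_dread"),
            params=dc.ModelParams(beta=2.0, gamma_p=0.9, alpha=0.5))
        data = dc.simulate_agent(pairs, agent, seed=6)
        p = dc.choice_curve(data).proportions
        assert abs(p["zero"] - 0.5) < 0.1
        assert p["zero"] > p["short"] > p["medium"] > p["long"]
        assert p["long"] < 0.4

    def test_counts_are_order_invariant(self, exp1_design):
        rng = np.random.default_rng(0)
        choices = rng.integers(0, 2, len(exp1_design))
        data = dc.ChoiceDataset.from_pairs("s", "pain", exp1_design, choices)
        perm = rng.permutation(len(exp1_design))
        shuffled = dc.ChoiceDataset.from_pairs(
            "s", "pain", [exp1_design[i] for i in perm], choices[perm])
        a, b = dc.choice_curve(data), dc.choice_curve(shuffled)
        assert a.n_later == b.n_later and a.n_total == b.n_total

    def test_empty_bin_flagged_nan(self):
        curve = curve_from_counts([5, 0, 0, 0], [10, 0, 0, 0])
        assert np.isnan(curve.proportions["short"])


class TestClassification:
    def test_flat_half_is_zero(self):
        curve = curve_from_counts([50, 50, 50, 50], [100, 100, 100, 100])
        assert dc.classify_time_preference(curve).label == "zero"

    def test_monotone_drop_is_negative(self):
        curve = curve_from_counts([25, 15, 8, 5], [50, 50, 50, 50])
        assert dc.classify_time_preference(curve).label == "negative"

    def test_uniformly_low_with_no_trend_is_negative(self):
        # the theoretical 0.5 anchor at zero delay difference makes a flat
        # curve at 0.2 a significant decrease, not 'no change'
        curve = curve_from_counts([10, 10, 10, 0], [50, 50, 50, 0])
        assert dc.classify_time_preference(curve).label == "negative"

    def test_drop_then_rise_is_reversing(self):
        curve = curve_from_counts([25, 5, 5, 45], [50, 50, 50, 50])
        assert dc.classify_time_preference(curve).label == "reversing"

    def test_monotone_rise_is_positive(self):
        curve = curve_from_counts([25, 35, 42, 45], [50, 50, 50, 50])
        assert dc.classify_time_preference(curve).label == "positive"

    def test_single_bin_unclassifiable(self):
        curve = curve_from_counts([10, 0, 0, 0], [20, 0, 0, 0])
        assert dc.classify_time_preference(curve).label == "unclassifiable"

    @given(st.lists(st.tuples(st.integers(0, 60), st.integers(0, 60)),
                    min_size=4, max_size=4))
    def test_labels_exclusive_and_exhaustive(self, cells):
        """Every classifiable count table gets exactly one of the four
        phenotype labels."""
        later = [min(k, n) for k, n in cells]
        total = [n for _, n in cells]
        curve = curve_from_counts(later, total)
        label = dc.classify_time_preference(curve).label
        if sum(t > 0 for t in total) < 2:
            assert label == "unclassifiable"
        else:
            assert label in {"zero", "positive", "negative", "reversing"}


class TestFramingEffect:
    def make(self, n, f_sooner, frame):
        pair = dc.ChoicePair(dc.ChoiceOption(5, 4), dc.ChoiceOption(8, 20),
                             frame=frame)
        k = round(n * f_sooner)
        return dc.ChoiceDataset.from_pairs(
            "s", frame, [pair] * n, [0] * k + [1] * (n - k))

    def test_identical_frames_no_effect(self):
        res = dc.framing_effect_test(self.make(95, 0.7, "pain"),
                                     self.make(95, 0.7, "relief"))
        assert res.p_value == pytest.approx(1.0)
        assert res.direction == 0

    def test_p_matches_enumeration_oracle(self):
        res = dc.framing_effect_test(self.make(95, 0.74, "pain"),
                                     self.make(95, 0.67, "relief"))
        k1, k2 = round(95 * 0.74), round(95 * 0.67)
        assert res.p_value == pytest.approx(
            fisher_oracle(k1, 95, k2, 95), rel=1e-6)
        assert res.direction == 1

    def test_reverse_direction_flagged(self):
        res = dc.framing_effect_test(self.make(95, 0.30, "pain"),
                                     self.make(95, 0.80, "relief"))
        assert res.p_value < 0.05
        assert res.direction == -1


class TestConvenienceAnova:
    def test_repeated_measures_anova_runs(self):
        import pandas as pd
        rng = np.random.default_rng(1)
        rows = [
            {"subject": f"s{i}", "frame": f, "bin": b,
             "prop": float(np.clip(0.5 + rng.normal(0, 0.1), 0, 1))}
            for i in range(6) for f in ("pain", "relief")
            for b in ("short", "medium", "long")
        ]
        tab = dc.behavior.repeated_measures_anova(
            pd.DataFrame(rows), dv="prop", subject="subject",
            within=["frame", "bin"])
        assert "F Value" in tab.columns
        assert set(tab.index) >= {"frame", "bin"}


class TestExclusions:
    def frame_data(self, frame, choices):
        pair = dc.ChoicePair(dc.ChoiceOption(5, 4), dc.ChoiceOption(8, 20),
                             frame=frame)
        return dc.ChoiceDataset.from_pairs("s", frame, [pair] * len(choices),
                                           choices)

    def test_max_dreader_one_frame_excluded(self):
        cohort = {"s0": {"datasets": [self.frame_data("pain", [0] * 95),
                                      self.frame_data("relief", [0] * 94 + [1])],
                         "max_rate_rating": 7.0}}
        included, excluded = dc.apply_exclusions(cohort)
        assert included == []
        assert excluded[0]["reason"] == "max_dreader"

    def test_adaptation_rating_excluded(self):
        cohort = {"s0": {"datasets": [self.frame_data("pain", [0, 1] * 20)],
                         "max_rate_rating": 3.0}}
        _, excluded = dc.apply_exclusions(cohort)
        assert excluded[0]["reason"] == "adaptation"

    def test_99_percent_sooner_included(self):
        choices = [0] * 94 + [1]
        cohort = {"s0": {"datasets": [self.frame_data("pain", choices),
                                      self.frame_data("relief", choices)],
                         "max_rate_rating": 8.0}}
        included, excluded = dc.apply_exclusions(cohort)
        assert included == ["s0"] and excluded == []
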