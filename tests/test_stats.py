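"""Normality-gated routing, Fisher exact, Dunn post hoc, two-way ANOVA."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from clockmorph.stats import (
    GroupData,
    compare_groups,
    dunn_posthoc,
    fisher_exact_2x2,
    normality_gate,
    significance_stars,
    two_way_anova,
)
from oracles import fisher_p_by_enumeration, two_way_ss_by_hand


def groups_from(*arrays, labels=None):
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    return [GroupData(l, tuple(a)) for l, a in zip(labels, arrays)]


class TestNormalityGate:
    def test_gaussian_samples_pass_most_of_the_time(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            gs = groups_from(*(rng.normal(0, 1, 50) for _ in range(3)))
            if normality_gate(gs) == "parametric":
                hits += 1
        assert hits >= 80  # expect ~ (0.95)^3 ~ 86%

    def test_heavy_tails_fail_the_gate(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            gs = groups_from(rng.standard_t(1, 50), rng.normal(0, 1, 50))
            if normality_gate(gs) == "nonparametric":
                hits += 1
        assert hits >= 45

    def test_small_group_is_an_error(self):
        gs = groups_from([1.0, 2.0, 3.0, 2.5, 1.5])
        with pytest.raises(ValueError, match="nonparametric"):
            normality_gate(gs)


class TestRouting:
    def test_two_gaussian_groups_use_t_test(self):
        rng = np.random.default_rng(0)
        report = compare_groups(
            groups_from(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        )
        assert report.chosen_test == "t-test"
        assert report.gate == "parametric"
        assert report.posthoc == []

    def test_two_heavy_tailed_groups_use_mann_whitney(self):
        rng = np.random.default_rng(2)
        report = compare_groups(
            groups_from(rng.standard_t(1, 30), rng.standard_t(1, 30))
        )
        assert report.chosen_test == "Mann-Whitney"

    def test_three_groups_route_to_anova_with_tukey(self):
        rng = np.random.default_rng(0)
        report = compare_groups(
            groups_from(*(rng.normal(0, 1, 25) for _ in range(3)))
        )
        assert report.chosen_test == "one-way ANOVA"
        assert len(report.posthoc) == 3  # k(k-1)/2

    def test_three_heavy_tailed_groups_route_to_kruskal_dunn(self):
        rng = np.random.default_rng(4)
        report = compare_groups(
            groups_from(*(rng.standard_t(1, 25) for _ in range(4)))
        )
        assert report.chosen_test == "Kruskal-Wallis"
        assert len(report.posthoc) == 6
        for pair in report.posthoc:
            assert pair.p_adjusted >= pair.p_raw - 1e-12

    def test_shifted_groups_detected_with_correct_direction(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)  # 5 sd shift
        report = compare_groups(groups_from(a, b))
        assert report.p_value < 1e-6
        assert report.statistic < 0  # first group mean below second

    def test_degenerate_groups_rejected(self):
        gs = groups_from([1.0] * 10, [1.0] * 10)
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups(gs, gate_override="nonparametric")

    def test_gate_override_bypasses_normality(self):
        gs = groups_from([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        report = compare_groups(gs, gate_override="nonparametric")
        assert report.chosen_test == "Mann-Whitney"


class TestDunn:
    def test_adjusted_p_dominates_raw(self, rng):
        gs = groups_from(*(rng.normal(i, 1, 15) for i in range(4)))
        for adjust in ("bonferroni", "holm"):
            for pair in dunn_posthoc(gs, adjust=adjust):
                assert pair.p_raw - 1e-12 <= pair.p_adjusted <= 1.0

    def test_separated_groups_flagged(self, rng):
        gs = groups_from(rng.normal(0, 1, 20), rng.normal(10, 1, 20),
                         rng.normal(0.1, 1, 20))
        res = {p.pair: p.p_adjusted for p in dunn_posthoc(gs)}
        assert res[("g0", "g1")] < 0.01
        assert res[("g0", "g2")] > 0.05


class TestFisherExact:
    def test_headline_rhythmicity_contrast(self):
        odds, p = fisher_exact_2x2(39, 1, 4, 36)
        assert p < 0.001
        assert odds > 1

    def test_symmetric_table_p_is_one(self):
        _, p = fisher_exact_2x2(10, 10, 10, 10)
        assert p == pytest.approx(1.0)

    def test_enumeration_oracle_on_all_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(
                fisher_p_by_enumeration(a, b, c, d), rel=1e-9
            ), (a, b, c, d)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(0, 0, 5, 5)


class TestTwoWayAnova:
    def test_balanced_2x2_matches_hand_computed_sums_of_squares(self, rng):
        values = rng.normal(0, 1, 24)
        fa = ["lo"] * 12 + ["hi"] * 12
        fb = (["t1"] * 6 + ["t2"] * 6) * 2
        report = two_way_anova(values, fa, fb)
        oracle = two_way_ss_by_hand(values, fa, fb)
        for effect in ("A", "B", "A:B"):
            assert report.effects[effect][0] == pytest.approx(
                oracle[effect], rel=1e-9
            )

    def test_programmed_main_effect_detected(self):
        hits_a, hits_b = 0, 0
        for rep in range(40):
            rng = np.random.default_rng(300 + rep)
            fa = ["lo"] * 12 + ["hi"] * 12
            fb = (["t1"] * 6 + ["t2"] * 6) * 2
            shift = np.where(np.array(fa) == "hi", 2.0, 0.0)
            values = rng.normal(0, 1, 24) + shift
            report = two_way_anova(values, fa, fb)
            if report.effects["A"][1] < 0.05:
                hits_a += 1
            if report.effects["B"][1] < 0.05:
                hits_b += 1
        assert hits_a >= 36  # >= 90% power on the programmed factor
        assert hits_b <= 8  # no spurious factor-B effect

    def test_single_replicate_cell_is_an_error(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        fa = ["x", "x", "y", "y", "y"]
        fb = ["u", "v", "u", "u", "v"]  # (x, v) has one replicate
        with pytest.raises(ValueError, match=r"\(x, v\)"):
            two_way_anova(values, fa, fb)


def test_significance_tiers():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
    assert significance_stars(0.5) == "ns"
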