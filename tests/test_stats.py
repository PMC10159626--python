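import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormmem.datamodel import EndpointCounts
from wormmem.stats import (
    StatTest,
    behavior_indices,
    ci_filter,
    classify_responders,
    comparison_table,
    count_upward_crossings,
    one_sample_vs_zero,
    pairwise_test,
    pfdr_adjust,
)


class TestComparisonTable:
    def test_exchange_design_has_eight_rows(self):
        specs = comparison_table("but_da_exchange")
        assert len(specs) == 8
        assert specs[0].group_a.short == "STAP-T"
        assert specs[0].group_b.short == "STAV-T"

    def test_exposure_design_has_eighteen_rows(self):
        specs = comparison_table("but_exposure")
        assert len(specs) == 18
        # the long-term block extends, it does not replace
        assert specs[:8] == comparison_table("but_da_exchange")

    def test_all_specs_have_distinct_groups(self):
        for spec in comparison_table("but_exposure"):
            assert spec.group_a != spec.group_b

    def test_component_labels_cover_the_design(self):
        labels = {s.component_label for s in comparison_table("but_exposure")}
        assert labels == {"CS", "US+", "US-", "VAL", "TR", "SL"}

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            comparison_table("nope")


class TestCiFilter:
    def test_all_equal_excludes_nothing(self):
        kept, excluded = ci_filter(np.full(10, 7.0))
        assert excluded == [] and kept.size == 10

    def test_gross_outlier_excluded(self):
        vals = np.array([0.0] * 9 + [100.0])
        # oracle by hand: mean 10, sd 31.6; 100 > 10 + 1.96*31.6 = 72.0
        kept, excluded = ci_filter(vals)
        assert excluded == [9]
        assert kept.size == 9

    def test_small_group_passes_through(self):
        vals = np.array([1.0, 100.0])
        kept, excluded = ci_filter(vals)
        assert excluded == [] and kept.size == 2


class TestPairwiseTest:
    def test_identical_groups_null(self, rng):
        a = rng.normal(size=12)
        test, _, p = pairwise_test(a, a)
        assert p > 0.99

    def test_separated_normals_use_t(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(5, 1, 10)
        test, stat, p = pairwise_test(a, b)
        assert test is StatTest.t
        assert p < 1e-3
        # closed-form two-sample t oracle
        sp = np.sqrt(((a.var(ddof=1) * 9) + (b.var(ddof=1) * 9)) / 18)
        t_oracle = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 10))
        assert stat == pytest.approx(t_oracle, rel=1e-9)

    def test_skewed_sample_switches_to_rank_sum(self, rng):
        from scipy import stats as sps
        # exponential sample that Shapiro-Wilk rejects at alpha = 0.05
        for _ in range(50):
            a = rng.exponential(size=10)
            if sps.shapiro(a).pvalue < 0.05:
                break
        b = rng.normal(size=10)
        test, _, _ = pairwise_test(a, b)
        assert test is StatTest.rank_sum

    def test_paired_flag_honored(self, rng):
        a = rng.normal(size=10)
        b = a + rng.normal(0.5, 0.1, size=10)
        test, _, p = pairwise_test(a, b, paired=True)
        assert test in (StatTest.t, StatTest.signed_rank)
        assert p < 0.01
        with pytest.raises(ValueError, match="equal-length"):
            pairwise_test(a, b[:5], paired=True)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPfdr:
    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(pfdr_adjust([1.0] * 5), 1.0)
        np.testing.assert_allclose(pfdr_adjust([1.0] * 5, method="bh"), 1.0)

    def test_bh_hand_step_up(self):
        # hand step-up on {0.01, 0.02, 0.9}: q3 = 0.9; q2 = min(0.02*3/2, 0.9)
        # = 0.03; q1 = min(0.01*3/1, 0.03) = 0.03
        q = pfdr_adjust([0.01, 0.02, 0.9], method="bh")
        np.testing.assert_allclose(q, [0.03, 0.03, 0.9])

    def test_storey_equals_bh_scaled_by_pi0(self):
        p = np.array([0.01, 0.2, 0.4, 0.6, 0.8, 0.9])
        # pi0 = #{p > 0.5} / (0.5 * 6) = 3/3 = 1 -> storey == bh here
        np.testing.assert_allclose(pfdr_adjust(p), pfdr_adjust(p, method="bh"))
        p2 = np.array([0.01, 0.02, 0.03, 0.04, 0.6, 0.9])
        # pi0 = 2/3 < 1 -> storey q-values below BH
        assert np.all(pfdr_adjust(p2) <= pfdr_adjust(p2, method="bh") + 1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_q_monotone_in_p(self, pvals):
        p = np.asarray(pvals)
        for method in ("storey", "bh"):
            q = pfdr_adjust(p, method=method)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)
            assert np.all((q >= 0) & (q <= 1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            pfdr_adjust([0.5, 1.5])


class TestBehaviorIndices:
    def test_full_attraction_is_plus_one(self):
        idx = behavior_indices(EndpointCounts(120, 0), EndpointCounts(60, 60),
                               EndpointCounts(60, 60))
        assert idx.CI_trained == 1.0

    def test_complete_aversion_is_minus_one(self):
        idx = behavior_indices(EndpointCounts(0, 120), EndpointCounts(60, 60),
                               EndpointCounts(60, 60))
        assert idx.CI_trained == -1.0

    def test_direct_arithmetic(self):
        idx = behavior_indices(EndpointCounts(75, 25), EndpointCounts(50, 50),
                               EndpointCounts(40, 60))
        assert idx.CI_trained == pytest.approx(0.5)
        assert idx.LI_stimulus == pytest.approx(0.5 - 0.0)
        assert idx.LI_training == pytest.approx(0.5 - (-0.2))
        assert idx.LI_treatment == pytest.approx(0.0 - (-0.2))

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_endpoint_swap(self, n_cs, n_alt):
        if n_cs + n_alt == 0:
            return
        even = EndpointCounts(50, 50)
        a = behavior_indices(EndpointCounts(n_cs, n_alt), even, even).CI_trained
        b = behavior_indices(EndpointCounts(n_alt, n_cs), even, even).CI_trained
        assert a == pytest.approx(-b)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            behavior_indices(EndpointCounts(0, 0), EndpointCounts(1, 0),
                             EndpointCounts(1, 0))


class TestOneSampleVsZero:
    def test_all_zero_gives_one(self):
        assert one_sample_vs_zero(np.zeros(5)) == 1.0

    def test_consistent_nonzero_is_significant(self, rng):
        vals = 1.0 + rng.normal(0, 0.01, size=4)
        p = one_sample_vs_zero(vals)
        assert p < 0.01

    def test_symmetric_values_not_significant(self):
        p = one_sample_vs_zero(np.array([-1.0, 1.0, -1.0, 1.0]))
        assert p > 0.9


class TestResponderClassification:
    def test_flat_trace_not_responding(self):
        flags = classify_responders([np.zeros(20)], threshold=0.5, mode="trial")
        assert flags == [False]

    def test_square_pulse_counts_one_crossing(self):
        pulse = np.concatenate([np.zeros(5), np.ones(5), np.zeros(5)])
        assert count_upward_crossings(pulse, 0.5) == 1

    def test_single_crossing_animal_vs_trial_modes(self):
        pulse = np.concatenate([np.zeros(5), np.ones(5), np.zeros(5)])
        trials = [pulse] + [np.zeros(15)] * 5
        assert classify_responders(trials, 0.5, mode="trial") == [True] + [False] * 5
        assert classify_responders(trials, 0.5, mode="animal") is False
        assert classify_responders([pulse] * 2 + [np.zeros(15)] * 4, 0.5,
                                   mode="animal") is True

    def test_animal_mode_needs_six_trials(self):
        with pytest.raises(ValueError, match="6 trials"):
            classify_responders([np.zeros(10)] * 5, 0.5, mode="animal")
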