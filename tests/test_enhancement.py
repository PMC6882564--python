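"""Enhancement computation, attainment counting and arm comparisons."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdose import (
    MeasurementError,
    attainment_rate,
    chi_square_2x2,
    compute_enhancement,
    compute_enhancements,
    two_sample_t,
)
from ctdose.cohort import PatientRecord, moment_match


def make_record(aorta_unenh=40.0, aorta_hap=380.0, lobes_unenh=(55.0, 57.0),
                lobes_pvp=(110.0, 116.0)):
    return PatientRecord(
        patient_id="p1", protocol_kvp=120, sex="M", age=70.0, height_cm=160.0,
        weight_kg=55.0, administered_ml_per_kg=2.0,
        aorta_unenh_hu=aorta_unenh, aorta_hap_hu=aorta_hap,
        liver_r_unenh_hu=lobes_unenh[0], liver_l_unenh_hu=lobes_unenh[1],
        liver_r_pvp_hu=lobes_pvp[0], liver_l_pvp_hu=lobes_pvp[1],
    )


class TestComputeEnhancement:
    def test_aorta_is_post_minus_unenhanced(self):
        assert compute_enhancement(make_record()).aorta_enh == pytest.approx(340.0)

    def test_liver_averages_lobes_before_subtraction(self):
        # mean(110, 116) - mean(55, 57) = 113 - 56 = 57
        assert compute_enhancement(make_record()).liver_enh == pytest.approx(57.0)

    def test_moment_matched_cohort_reproduces_arm_moments(self, cohort_120):
        enh = compute_enhancements(cohort_120)
        a = np.array([e.aorta_enh for e in enh])
        assert a.mean() == pytest.approx(340.9, abs=1e-9)
        assert a.std(ddof=1) == pytest.approx(51.4, abs=1e-9)

    def test_missing_field_names_the_field(self):
        record = dataclasses.replace(make_record(), aorta_hap_hu=float("nan"))
        with pytest.raises(MeasurementError, match="aorta_hap_hu"):
            compute_enhancement(record)

    def test_nonpositive_enhancement_is_flagged_not_dropped(self):
        record = make_record(aorta_unenh=400.0, aorta_hap=380.0)
        sample = compute_enhancement(record)
        assert sample.aorta_enh == pytest.approx(-20.0)
        assert sample.flags == ("aorta",)

    @given(shift=st.floats(-500, 500))
    @settings(max_examples=30, deadline=None)
    def test_baseline_shift_cancels(self, shift):
        base = compute_enhancement(make_record())
        shifted = compute_enhancement(
            make_record(aorta_unenh=40 + shift, aorta_hap=380 + shift,
                        lobes_unenh=(55 + shift, 57 + shift),
                        lobes_pvp=(110 + shift, 116 + shift))
        )
        assert shifted.aorta_enh == pytest.approx(base.aorta_enh, abs=1e-9)
        assert shifted.liver_enh == pytest.approx(base.liver_enh, abs=1e-9)


class TestAttainment:
    def test_counts_strictly_above_threshold(self):
        k, n, rate = attainment_rate([300.0, 250.0, 290.0], 280.0)
        assert (k, n) == (2, 3)
        assert rate == pytest.approx(2 / 3)

    def test_values_at_threshold_do_not_count(self):
        k, n, rate = attainment_rate([280.0] * 10, 280.0)
        assert (k, n, rate) == (0, 10, 0.0)

    def test_matches_gaussian_tail_at_large_n(self, rng):
        from scipy.stats import norm

        x = rng.normal(340.9, 51.4, size=10_000)
        rate = attainment_rate(x, 280.0).rate
        expected = norm.sf((280.0 - 340.9) / 51.4)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(rate - expected) < 3 * se

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            attainment_rate([], 280.0)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotone_nonincreasing_in_threshold(self, data):
        values = data.draw(st.lists(st.floats(0, 500), min_size=1, max_size=30))
        t1 = data.draw(st.floats(0, 500))
        t2 = data.draw(st.floats(0, 500))
        lo, hi = min(t1, t2), max(t1, t2)
        assert attainment_rate(values, lo).rate >= attainment_rate(values, hi).rate


class TestTwoSampleT:
    def test_identical_groups_give_zero_statistic(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.degrees_of_freedom == 4

    def test_matches_hand_computed_pooled_formula(self):
        # {1,2,3} vs {4,5,6}: pooled s^2 = 1, t = -3/sqrt(2/3)
        res = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-9)
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)

    def test_arm_difference_is_significant_at_published_moments(self, rng):
        a = moment_match(rng.normal(size=100), 340.9, 51.4)
        b = moment_match(rng.normal(size=100), 395.9, 65.1)
        assert two_sample_t(a, b).p_value < 0.01

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=20), rng.normal(1.0, 2.0, size=25)
        fwd, rev = two_sample_t(a, b), two_sample_t(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_welch_variant_reports_fractional_df(self, rng):
        a, b = rng.normal(size=10), rng.normal(0, 5.0, size=40)
        res = two_sample_t(a, b, pooled=False)
        assert res.test_name == "welch-t"
        assert res.degrees_of_freedom != 48

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0, 1.0], [2.0, 2.0])


class TestChiSquare:
    def test_identical_ratios_give_zero_statistic(self):
        res = chi_square_2x2((50, 50), (50, 50))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.degrees_of_freedom == 1

    def test_matches_hand_computed_pearson_formula(self):
        # expected counts 55/45 per cell group; chi2 = 4*25*(1/55+1/45)/2
        res = chi_square_2x2((60, 40), (50, 50))
        assert res.statistic == pytest.approx(2.0202, abs=1e-3)
        assert res.p_value == pytest.approx(0.1553, abs=1e-3)

    def test_extreme_imbalance_is_highly_significant(self):
        assert chi_square_2x2((10, 90), (90, 10)).p_value < 1e-6

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2((0, 50), (0, 50))
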