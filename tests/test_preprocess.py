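"""Quality grading, DST repair, the exclusion funnel and hourly aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import actiprofiles as ap
from actiprofiles.preprocess import round_half_up, week_slots

EPH = 12  # epochs per hour at the 300 s test resolution


def make_series(values, epoch_seconds=300, imputed=None, pid="p1",
                start="2015-06-01"):
    values = np.asarray(values, dtype=float)
    return ap.EpochSeries(
        participant_id=pid,
        start_timestamp=pd.Timestamp(start),
        epoch_seconds=epoch_seconds,
        values=values,
        imputed=np.zeros(values.size, bool) if imputed is None else imputed,
    )


def constant_week(level=50.0, epoch_seconds=300):
    return make_series(np.full(week_slots(epoch_seconds), level),
                       epoch_seconds=epoch_seconds)


class TestClassifyQuality:
    def test_complete_perfect(self):
        assert ap.classify_quality(constant_week()) \
            is ap.QualityCategory.COMPLETE_PERFECT

    def test_complete_imputed_needs_a_flag(self):
        series = constant_week()
        series.imputed[100] = True
        assert ap.classify_quality(series) is ap.QualityCategory.COMPLETE_IMPUTED

    def test_recoverable_is_one_blank(self):
        series = constant_week()
        series.values[-1] = np.nan
        assert ap.classify_quality(series) is ap.QualityCategory.RECOVERABLE

    def test_spring_dst_needs_full_blank_hour(self):
        values = np.full(week_slots(300) + EPH, 40.0)
        values[25 * EPH:26 * EPH] = np.nan
        assert ap.classify_quality(make_series(values)) \
            is ap.QualityCategory.DST_SPRING

    def test_autumn_dst_by_slot_count(self):
        values = np.full(week_slots(300) - EPH, 40.0)
        assert ap.classify_quality(make_series(values)) \
            is ap.QualityCategory.DST_AUTUMN

    @pytest.mark.parametrize("n_blank", [2, 50])
    def test_multiple_blanks_are_unusable(self, n_blank):
        series = constant_week()
        series.values[:n_blank] = np.nan
        assert ap.classify_quality(series) is ap.QualityCategory.UNUSABLE

    def test_malformed_series_raises_not_unusable(self):
        with pytest.raises(ValueError):
            make_series([-1.0] * week_slots(300))


class TestRepairDst:
    def test_spring_repair_constant_fill_and_slot_count(self):
        values = np.full(week_slots(300) + EPH, 30.0)
        blank_hour = 25
        values[blank_hour * EPH:(blank_hour + 1) * EPH] = np.nan
        series = make_series(values)
        repaired = ap.repair_dst(series, ap.QualityCategory.DST_SPRING)
        assert repaired.n_slots == week_slots(300)
        np.testing.assert_array_equal(
            repaired.values[blank_hour * EPH:(blank_hour + 1) * EPH], 30.0)
        assert repaired.imputed.sum() == EPH

    def test_spring_repair_uses_same_clock_hour(self):
        # value depends on the day: clock hour 1 is 10*(day+1) mg
        values = np.full(week_slots(300) + EPH, 5.0)
        for day in range(7):
            h = day * 24 + 1
            values[h * EPH:(h + 1) * EPH] = 10.0 * (day + 1)
        blank_hour = 3 * 24 + 1  # Thursday 01:00 goes blank
        values[blank_hour * EPH:(blank_hour + 1) * EPH] = np.nan
        repaired = ap.repair_dst(make_series(values),
                                 ap.QualityCategory.DST_SPRING)
        expected = np.mean([10.0 * (d + 1) for d in range(7) if d != 3])
        np.testing.assert_allclose(
            repaired.values[blank_hour * EPH:(blank_hour + 1) * EPH], expected)

    def test_autumn_repair_appends_final_hour(self):
        values = np.full(week_slots(300) - EPH, 42.0)
        repaired = ap.repair_dst(make_series(values),
                                 ap.QualityCategory.DST_AUTUMN)
        assert repaired.n_slots == week_slots(300)
        np.testing.assert_array_equal(repaired.values[-EPH:], 42.0)
        assert repaired.imputed[-EPH:].all()

    def test_repaired_series_classifies_as_complete(self):
        values = np.full(week_slots(300) - EPH, 42.0)
        repaired = ap.repair_dst(make_series(values),
                                 ap.QualityCategory.DST_AUTUMN)
        assert ap.classify_quality(repaired) \
            is ap.QualityCategory.COMPLETE_IMPUTED

    def test_non_dst_category_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="DST"):
            ap.repair_dst(constant_week(), ap.QualityCategory.RECOVERABLE)


class TestWearHours:
    def test_complete_week_is_168_hours(self):
        assert ap.nonimputed_wear_hours(constant_week()) == 168.0

    def test_half_imputed_week_is_84_hours(self):
        series = constant_week()
        series.imputed[:series.n_slots // 2] = True
        assert ap.nonimputed_wear_hours(series) == 84.0


class TestHourlyAggregate:
    def test_constant_series_gives_constant_hours(self):
        profile = ap.hourly_aggregate(constant_week(50.0))
        np.testing.assert_array_equal(profile.hours, 50.0)
        np.testing.assert_array_equal(profile.epochs_per_hour_used, EPH)

    def test_recoverable_week_uses_one_fewer_epoch_in_one_hour(self):
        series = constant_week()
        series.values[-1] = np.nan
        profile = ap.hourly_aggregate(series)
        counts = profile.epochs_per_hour_used
        assert (counts == EPH).sum() == 167
        assert (counts == EPH - 1).sum() == 1

    def test_balanced_hour_means_midpoint(self):
        series = constant_week()
        series.values[:EPH // 2] = 0.0
        series.values[EPH // 2:EPH] = 100.0
        assert ap.hourly_aggregate(series).hours[0] == 50.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.0, 10.0), seed=st.integers(0, 10_000))
    def test_aggregation_commutes_with_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 100, week_slots(300))
        base = ap.hourly_aggregate(make_series(values))
        scaled = ap.hourly_aggregate(make_series(values * scale))
        np.testing.assert_allclose(scaled.hours, base.hours * scale,
                                   rtol=1e-12, atol=1e-12)


class TestAlignWeek:
    def test_monday_start_is_identity(self):
        profile = ap.hourly_aggregate(constant_week())
        profile.hours[:] = np.arange(168.0)
        aligned = ap.align_week(profile, "monday")
        np.testing.assert_array_equal(aligned.hours, profile.hours)

    def test_wednesday_start_rotates_by_48(self):
        profile = ap.hourly_aggregate(constant_week())
        profile.hours[:] = np.arange(168.0)
        aligned = ap.align_week(profile, "wednesday")
        # hour 0 of a Wednesday recording lands at Wednesday 00:00 = index 48
        assert aligned.hours[48] == 0.0
        np.testing.assert_array_equal(aligned.hours,
                                      np.roll(profile.hours, 48))

    def test_align_is_idempotent(self):
        profile = ap.hourly_aggregate(constant_week())
        once = ap.align_week(profile, 3)
        twice = ap.align_week(once)
        np.testing.assert_array_equal(once.hours, twice.hours)


class TestApplyExclusions:
    def test_mean_at_threshold_is_excluded_and_wear_at_threshold_retained(self):
        at_mean = constant_week(100.0)
        at_mean.participant_id = "mean100"
        at_wear = constant_week(30.0)
        at_wear.participant_id = "wear72"
        at_wear.imputed[:96 * EPH] = True  # exactly 72 h of measured wear
        retained, report = ap.apply_exclusions([at_mean, at_wear])
        ids = [s.participant_id for s in retained]
        assert ids == ["wear72"]
        assert report.n_mean_ge_threshold == 1
        assert report.n_wear_lt_threshold == 0

    def test_metadata_withdrawn_and_age(self):
        cohort = []
        for pid in ("ok", "gone", "young"):
            s = constant_week(30.0)
            s.participant_id = pid
            cohort.append(s)
        metadata = pd.DataFrame({
            "participant_id": ["ok", "gone", "young"],
            "withdrawn": [False, True, False],
            "age": [55, 50, 38],
        })
        retained, report = ap.apply_exclusions(cohort, metadata)
        assert [s.participant_id for s in retained] == ["ok"]
        assert report.n_withdrawn == 1
        assert report.n_age_ineligible == 1
        assert report.reasons["young"] == ["age_ineligible"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_funnel_conserves_counts_on_fuzzed_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        cohort, qualities = [], []
        for i in range(rng.integers(3, 12)):
            s = constant_week(float(rng.uniform(5, 120)))
            s.participant_id = f"f{i}"
            if rng.random() < 0.3:
                s.imputed[:rng.integers(0, s.n_slots)] = True
            if rng.random() < 0.2:
                s.values[: 1 + rng.integers(0, 5)] = np.nan
            cohort.append(s)
            qualities.append(ap.classify_quality(s))
        withdrawn = rng.random(len(cohort)) < 0.2
        metadata = pd.DataFrame({
            "participant_id": [s.participant_id for s in cohort],
            "withdrawn": withdrawn,
        })
        retained, report = ap.apply_exclusions(cohort, metadata, qualities)
        report.check_conservation()  # raises on an inconsistent funnel
        assert report.n_retained == len(retained)
        assert report.n_supplied == len(cohort)


class TestFunnelPercentages:
    def test_report_percentage_arithmetic(self):
        report = ap.ExclusionReport(
            n_supplied=1000, n_withdrawn=5, n_age_ineligible=15,
            category_counts={"complete_perfect": 800, "unusable": 80},
            n_suitability_excluded=100, n_retained=800)
        report.check_conservation()
        assert report.pct_available_of_supplied() == 98.0
        assert round_half_up(report.pct_usable_of_available(), 1) == 91.8
        assert report.pct_retained_of_supplied() == 80.0

    def test_round_half_up_matches_table_convention(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(16.56, 0) == 17.0
        assert round_half_up(-0.05, 1) == -0.1


class TestZeroNoisePipeline:
    def test_aligned_profiles_equal_templates_exactly(self, templates):
        # complete and one-blank weeks lose no cross-day information, so the
        # aligned zero-noise profiles reproduce the templates to within
        # floating tolerance
        config = ap.CohortConfig(
            n_per_archetype=2, epoch_seconds=300, noise_sd=0.0, seed=3,
            n_outliers_high_mean=0, n_low_wear=0,
            missingness_mix={"none": 0.5, "trailing_blank": 0.5})
        profiles, report = ap.preprocess_cohort(
            s for s, _ in ap.iter_cohort(config))
        assert report.n_retained == 18
        for profile in profiles:
            name = profile.participant_id.rsplit("_", 1)[0]
            np.testing.assert_allclose(profile.hours, templates[name],
                                       atol=1e-9)

    def test_dst_repair_error_confined_to_imputed_hour(self, templates):
        # same-clock-hour imputation is cross-day, so weekday/weekend
        # asymmetry leaves a small night-hour discrepancy and nothing else
        config = ap.CohortConfig(
            n_per_archetype=1, epoch_seconds=300, noise_sd=0.0, seed=4,
            n_outliers_high_mean=0, n_low_wear=0,
            missingness_mix={"spring_dst": 0.5, "autumn_dst": 0.5})
        profiles, _ = ap.preprocess_cohort(
            s for s, _ in ap.iter_cohort(config))
        for profile in profiles:
            name = profile.participant_id.rsplit("_", 1)[0]
            err = np.abs(profile.hours - templates[name])
            assert (err > 1e-9).sum() <= 1
            assert err.max() < 3.0  # night hours differ little across days
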