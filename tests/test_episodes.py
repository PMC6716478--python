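import itertools
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from adhema import episodes as epi
from adhema.types import DailyRecord, StudyConfig
from conftest import report
from oracles import episode_starts_brute, initial_exacerbation_end_brute


class TestSymptomDays:
    def test_cough_alone_flags_symptom_day(self, config):
        flags = epi.classify_symptom_days([report(cough=1, wheeze=0)], config)
        assert flags[date(2015, 8, 1)] is True

    def test_all_zero_report_is_nonsymptom_day(self, config):
        flags = epi.classify_symptom_days(
            [report(cough=0, wheeze=0, chest_tight=0, bored=3)], config
        )
        assert flags[date(2015, 8, 1)] is False

    def test_any_same_day_report_flags_the_day(self, config):
        reports = [
            report(ts="2015-08-01T09:00", cough=0, wheeze=0),
            report(ts="2015-08-01T20:00", wheeze=1),
        ]
        assert epi.classify_symptom_days(reports, config)[date(2015, 8, 1)]

    def test_days_without_report_are_absent(self, config):
        flags = epi.classify_symptom_days([report(cough=1)], config)
        assert date(2015, 8, 2) not in flags

    def test_mood_items_never_flag_symptoms(self, config):
        flags = epi.classify_symptom_days(
            [report(stressed=3, angry=3, bored=3)], config
        )
        assert flags[date(2015, 8, 1)] is False

    def test_threshold_is_configurable(self):
        strict = StudyConfig(symptom_threshold=2)
        flags = epi.classify_symptom_days([report(cough=1)], strict)
        assert flags[date(2015, 8, 1)] is False

    def test_same_day_reports_merge_by_item_maximum(self):
        reports = [
            report(ts="2015-08-01T09:00", cough=2, bored=1),
            report(ts="2015-08-01T20:00", cough=1, bored=3),
        ]
        merged = epi.merge_daily_responses(reports)
        assert merged[date(2015, 8, 1)] == {"cough": 2, "bored": 3}


class TestEpisodeDetection:
    def test_symptom_run_then_clear_then_recurrence(self, config):
        flags = {0: True, 1: True, 5: False, 10: True}
        result = epi.detect_new_episodes(flags, config, "P01")
        assert result.episode_start_days == [10]
        assert result.initial_exacerbation_end == 1
        assert result.episode_count == 1

    def test_symptoms_only_before_day_seven_never_qualify(self, config):
        result = epi.detect_new_episodes({0: True, 3: True}, config)
        assert result.episode_start_days == []
        assert result.initial_exacerbation_end == 3

    def test_two_separated_recurrences(self, config):
        flags = {2: False, 8: True, 12: False, 20: True}
        result = epi.detect_new_episodes(flags, config)
        assert result.episode_start_days == [8, 20]

    def test_first_ever_symptom_report_late_is_indeterminate(self, config):
        result = epi.detect_new_episodes({9: True, 11: True}, config)
        assert result.episode_start_days == []
        assert result.indeterminate_onset
        assert result.initial_exacerbation_end is None

    def test_consecutive_symptom_reports_share_one_episode(self, config):
        flags = {2: False, 8: True, 9: True, 10: True}
        result = epi.detect_new_episodes(flags, config)
        assert result.episode_start_days == [8]

    def test_threshold_day_is_configurable(self):
        config = StudyConfig(initial_exacerbation_days=3)
        result = epi.detect_new_episodes({0: False, 4: True}, config)
        assert result.episode_start_days == [4]

    def test_exhaustive_agreement_with_bruteforce_length_8(self, config):
        for seq in itertools.product((0, 1, 2), repeat=8):
            flags = {d: s == 2 for d, s in enumerate(seq) if s}
            result = epi.detect_new_episodes(flags, config)
            assert result.episode_start_days == episode_starts_brute(flags)
            assert (
                result.initial_exacerbation_end
                == initial_exacerbation_end_brute(flags)
            )

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=15))
    def test_invariants_on_arbitrary_sequences(self, seq):
        flags = {d: s == 2 for d, s in enumerate(seq) if s}
        result = epi.detect_new_episodes(flags, StudyConfig())
        starts = result.episode_start_days
        assert starts == sorted(set(starts))
        assert all(d >= 7 and flags[d] for d in starts)

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=14))
    def test_adding_clear_report_never_decreases_count(self, seq):
        flags = {d: s == 2 for d, s in enumerate(seq) if s}
        base = epi.detect_new_episodes(flags, StudyConfig()).episode_count
        for day in range(len(seq)):
            if day not in flags:
                augmented = dict(flags)
                augmented[day] = False
                count = epi.detect_new_episodes(
                    augmented, StudyConfig()
                ).episode_count
                assert count >= base

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=14))
    def test_deleting_clear_report_never_increases_count(self, seq):
        flags = {d: s == 2 for d, s in enumerate(seq) if s}
        base = epi.detect_new_episodes(flags, StudyConfig()).episode_count
        for day in [d for d, s in flags.items() if not s]:
            reduced = {d: s for d, s in flags.items() if d != day}
            count = epi.detect_new_episodes(
                reduced, StudyConfig()
            ).episode_count
            assert count <= base


def _make_records(pid, fractions):
    """Participant-days with prescribed has_ema/has_any_data patterns."""
    n, n_any, n_ema = fractions
    records = []
    for i in range(n):
        has_ema = i < n_ema
        has_any = i < n_any
        records.append(
            DailyRecord(
                pid,
                i,
                date(2015, 8, 1),
                has_ema=has_ema,
                has_any_data=has_any or has_ema,
            )
        )
    return records


class TestAcquisition:
    def test_cohort_fractions(self):
        # 681 participant-days, 606 with any data
        records = _make_records("P01", (341, 303, 70)) + _make_records(
            "P02", (340, 303, 66)
        )
        summary = epi.acquisition_metrics(records)
        assert summary.total_days == 681
        assert summary.any_data_days == 606
        assert summary.any_data_fraction == pytest.approx(606 / 681)
        assert round(summary.any_data_fraction * 100) == 89
        assert round(summary.ema_fraction * 100) == 20

    def test_zero_ema_participant_still_contributes_days(self):
        records = _make_records("P01", (10, 5, 0)) + _make_records(
            "P02", (10, 10, 10)
        )
        summary = epi.acquisition_metrics(records)
        assert summary.per_participant["P01"]["ema_fraction"] == 0.0
        assert summary.total_days == 20

    def test_ema_fraction_never_exceeds_any_data_fraction(self):
        records = _make_records("P01", (30, 20, 10)) + _make_records(
            "P02", (30, 5, 5)
        )
        summary = epi.acquisition_metrics(records)
        assert summary.ema_fraction <= summary.any_data_fraction <= 1
        for per in summary.per_participant.values():
            assert per["ema_fraction"] <= per["any_data_fraction"]

    def test_redesign_welch_comparison(self):
        records = []
        groups = {}
        for i in range(8):
            pid = f"P{i:02d}"
            groups[pid] = "pre" if i < 4 else "post"
            n_any = (8 + i) if i < 4 else (21 + i)
            records += _make_records(pid, (30, n_any, 2))
        summary = epi.acquisition_metrics(records, groups)
        any_cmp = next(
            r for r in summary.redesign if r.metric == "any_data_fraction"
        )
        assert any_cmp.post_mean > any_cmp.pre_mean
        assert any_cmp.p_value < 0.05

    def test_redesign_degenerate_group_flagged(self):
        records = _make_records("P01", (10, 5, 1))
        summary = epi.acquisition_metrics(records, {"P01": "pre"})
        assert all(cmp.undefined for cmp in summary.redesign)


class TestSubgroupTests:
    @staticmethod
    def _cohort(frac_by_pid, n_days=30):
        records = []
        for pid, frac in frac_by_pid.items():
            n_ema = int(round(frac * n_days))
            for i in range(n_days):
                records.append(
                    DailyRecord(
                        pid,
                        i,
                        date(2015, 8, 1) + pd.Timedelta(days=i).to_pytimedelta(),
                        has_ema=i < n_ema,
                        has_any_data=True,
                    )
                )
        return records

    def test_uniform_reporting_flags_degenerate_tests(self):
        records = self._cohort({"P01": 1.0, "P02": 1.0, "P03": 1.0})
        demo = pd.DataFrame(
            {
                "participant_id": ["P01", "P02", "P03"],
                "age": [9, 12, 15],
                "gender": ["female", "male", "female"],
            }
        )
        results = {r.name: r for r in epi.reporting_subgroup_tests(records, demo)}
        assert results["age"].undefined
        assert results["weekend_vs_weekday"].undefined

    def test_null_age_association_is_small_at_large_n(self):
        rng = np.random.default_rng(11)
        pids = [f"P{i:03d}" for i in range(60)]
        records = self._cohort(
            {pid: float(rng.uniform(0.1, 0.9)) for pid in pids}
        )
        demo = pd.DataFrame(
            {
                "participant_id": pids,
                "age": rng.integers(8, 17, size=60),
                "gender": rng.choice(["female", "male"], size=60),
            }
        )
        results = {r.name: r for r in epi.reporting_subgroup_tests(records, demo)}
        assert abs(results["age"].statistic) < 0.5

    def test_planted_gender_effect_detected_at_large_n(self):
        # female mean reporting 0.27 vs male 0.13, inflated sample size
        rng = np.random.default_rng(5)
        frac, gender, pids = {}, [], []
        for i in range(120):
            pid = f"P{i:03d}"
            pids.append(pid)
            g = "female" if i % 2 == 0 else "male"
            gender.append(g)
            mean = 0.27 if g == "female" else 0.13
            frac[pid] = float(np.clip(rng.normal(mean, 0.05), 0.0, 1.0))
        records = self._cohort(frac, n_days=100)
        demo = pd.DataFrame(
            {"participant_id": pids, "age": [10] * 120, "gender": gender}
        )
        results = {r.name: r for r in epi.reporting_subgroup_tests(records, demo)}
        gender_test = results["gender"]
        assert gender_test.detail["female_mean"] > gender_test.detail["male_mean"]
        assert gender_test.p_value < 1e-6
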