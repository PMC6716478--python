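"""Asthma-symptom-day classification, new-episode detection, acquisition.

A day is an *asthma symptom day* when any EMA report that day rates cough,
wheeze or chest tightness at or above the symptom threshold (default
"A little").  Days without a report are left undetermined — never coerced to
symptom-free.

A *new asthma symptom episode* starts at a symptom report on study day
``d`` when both hold:

1. ``d`` is at least the episode threshold (default 7 days post-enrollment);
2. at least one symptom-free EMA report lies strictly between the most
   recent prior symptom report (or enrollment, when none exists) and ``d``.

Consecutive symptom reports without an intervening symptom-free report
belong to one episode.  Symptoms reported from enrollment onward before any
symptom-free report constitute the *initial exacerbation*, not an episode;
a first-ever report that is already symptomatic at or past the threshold
day is flagged as an indeterminate onset and starts no episode (without an
interim clear report there is no evidence the prior episode had resolved).
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

import pandas as pd

from .types import (
    AcquisitionSummary,
    DailyRecord,
    EmaReport,
    EpisodeResult,
    RedesignComparison,
    SubgroupTestResult,
    SYMPTOM_ITEMS,
    StudyConfig,
)


def merge_daily_responses(
    reports: Iterable[EmaReport],
) -> dict[date, dict[str, int]]:
    """Merge same-day reports by per-item maximum."""
    merged: dict[date, dict[str, int]] = defaultdict(dict)
    for report in reports:
        day = report.timestamp.date()
        for item, level in report.responses.items():
            if level > merged[day].get(item, -1):
                merged[day][item] = level
    return dict(merged)


def classify_symptom_days(
    reports: Iterable[EmaReport],
    config: Optional[StudyConfig] = None,
) -> dict[date, bool]:
    """Per-day symptom flags for one participant's reports.

    Returns a mapping for *report days only*; absent days are undetermined.
    """
    config = (config or StudyConfig()).validate()
    threshold = config.symptom_threshold
    flags: dict[date, bool] = {}
    for day, responses in merge_daily_responses(reports).items():
        flags[day] = any(
            responses.get(item, 0) >= threshold for item in SYMPTOM_ITEMS
        )
    return flags


def detect_new_episodes(
    symptom_flags: Mapping[int, bool],
    config: Optional[StudyConfig] = None,
    participant_id: str = "",
) -> EpisodeResult:
    """Scan per-study-day symptom flags and detect new symptom episodes.

    ``symptom_flags`` maps study day → True (symptomatic report) / False
    (symptom-free report); days without a report are simply absent.
    """
    config = (config or StudyConfig()).validate()
    min_day = config.initial_exacerbation_days

    episodes: list[int] = []
    initial_end: Optional[int] = None
    indeterminate = False
    any_report = False
    in_initial = False
    clear_since_symptom = False  # symptom-free report since last symptom report

    for day in sorted(symptom_flags):
        symptomatic = symptom_flags[day]
        if not symptomatic:
            clear_since_symptom = True
            in_initial = False
            any_report = True
            continue
        if not any_report:
            if day < min_day:
                in_initial = True
                initial_end = day
            else:
                indeterminate = True
        elif in_initial:
            initial_end = day
        elif clear_since_symptom and day >= min_day:
            episodes.append(day)
        clear_since_symptom = False
        any_report = True
    return EpisodeResult(
        participant_id=participant_id,
        initial_exacerbation_end=initial_end,
        episode_start_days=episodes,
        indeterminate_onset=indeterminate,
    )


# ---------------------------------------------------------------------------
# acquisition metrics
# ---------------------------------------------------------------------------


def _welch(a: Sequence[float], b: Sequence[float]) -> tuple[Optional[float], Optional[float], bool]:
    if len(a) < 2 or len(b) < 2:
        return None, None, True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(t):
        return None, None, True
    return float(t), float(p), False


def acquisition_metrics(
    records: Iterable[DailyRecord],
    redesign_groups: Optional[Mapping[str, str]] = None,
) -> AcquisitionSummary:
    """Cohort data-acquisition summary.

    ``redesign_groups`` optionally maps participant_id → ``"pre"``/``"post"``
    (enrollment before/after the app redesign); when given, per-participant
    percent-of-days-with-data values are compared between groups with Welch
    t-tests, for both the any-data and the EMA metric.
    """
    per: dict[str, dict[str, float]] = {}
    by_pid: dict[str, list[DailyRecord]] = defaultdict(list)
    for rec in records:
        by_pid[rec.participant_id].append(rec)

    total = any_data = ema = 0
    for pid, recs in by_pid.items():
        n = len(recs)
        n_any = sum(r.has_any_data for r in recs)
        n_ema = sum(r.has_ema for r in recs)
        total += n
        any_data += n_any
        ema += n_ema
        per[pid] = {
            "days": n,
            "any_data_fraction": n_any / n if n else float("nan"),
            "ema_fraction": n_ema / n if n else float("nan"),
        }

    redesign: list[RedesignComparison] = []
    if redesign_groups is not None:
        for metric in ("any_data_fraction", "ema_fraction"):
            pre = [
                per[pid][metric]
                for pid in per
                if redesign_groups.get(pid) == "pre"
            ]
            post = [
                per[pid][metric]
                for pid in per
                if redesign_groups.get(pid) == "post"
            ]
            t, p, undefined = _welch(pre, post)
            redesign.append(
                RedesignComparison(
                    metric=metric,
                    pre_mean=statistics.fmean(pre) if pre else float("nan"),
                    post_mean=statistics.fmean(post) if post else float("nan"),
                    n_pre=len(pre),
                    n_post=len(post),
                    t_stat=t,
                    p_value=p,
                    undefined=undefined,
                )
            )

    return AcquisitionSummary(
        total_days=total,
        any_data_days=any_data,
        ema_days=ema,
        any_data_fraction=any_data / total if total else float("nan"),
        ema_fraction=ema / total if total else float("nan"),
        per_participant=per,
        redesign=redesign,
    )


# ---------------------------------------------------------------------------
# reporting-frequency subgroup tests
# ---------------------------------------------------------------------------


def reporting_subgroup_tests(
    records: Iterable[DailyRecord],
    demographics: pd.DataFrame,
) -> list[SubgroupTestResult]:
    """EMA reporting-frequency differences by age, gender and weekend/weekday.

    ``demographics`` needs columns ``participant_id``, ``age`` (years) and
    ``gender`` (``female``/``male``, case-insensitive).  Age uses a Pearson
    correlation against the per-participant report fraction; gender a Welch
    t-test; weekend-vs-weekday a paired t-test on each participant's
    (weekend fraction, weekday fraction) pair.
    """
    by_pid: dict[str, list[DailyRecord]] = defaultdict(list)
    for rec in records:
        by_pid[rec.participant_id].append(rec)

    frac: dict[str, float] = {}
    weekend_frac: dict[str, float] = {}
    weekday_frac: dict[str, float] = {}
    for pid, recs in by_pid.items():
        frac[pid] = sum(r.has_ema for r in recs) / len(recs)
        wend = [r for r in recs if r.date.weekday() >= 5]
        wday = [r for r in recs if r.date.weekday() < 5]
        if wend and wday:
            weekend_frac[pid] = sum(r.has_ema for r in wend) / len(wend)
            weekday_frac[pid] = sum(r.has_ema for r in wday) / len(wday)

    demo = demographics.set_index(demographics["participant_id"].astype(str))
    results: list[SubgroupTestResult] = []

    # age: Pearson correlation
    pids = [p for p in frac if p in demo.index]
    ages = np.array([float(demo.loc[p, "age"]) for p in pids])
    fracs = np.array([frac[p] for p in pids])
    if len(pids) >= 3 and np.std(ages) > 0 and np.std(fracs) > 0:
        r, p = stats.pearsonr(ages, fracs)
        results.append(
            SubgroupTestResult("age", float(r), float(p), {"n": len(pids)})
        )
    else:
        results.append(
            SubgroupTestResult("age", None, None, {"n": len(pids)}, undefined=True)
        )

    # gender: Welch t-test
    female = [
        frac[p]
        for p in pids
        if str(demo.loc[p, "gender"]).strip().lower() == "female"
    ]
    male = [
        frac[p]
        for p in pids
        if str(demo.loc[p, "gender"]).strip().lower() == "male"
    ]
    t, p, undefined = _welch(female, male)
    results.append(
        SubgroupTestResult(
            "gender",
            t,
            p,
            {
                "female_mean": statistics.fmean(female) if female else float("nan"),
                "male_mean": statistics.fmean(male) if male else float("nan"),
                "n_female": len(female),
                "n_male": len(male),
            },
            undefined=undefined,
        )
    )

    # weekend vs weekday: paired t-test
    paired = sorted(weekend_frac)
    a = np.array([weekend_frac[p] for p in paired])
    b = np.array([weekday_frac[p] for p in paired])
    if len(paired) >= 2 and np.std(a - b) > 0:
        t_stat, p_value = stats.ttest_rel(a, b)
        results.append(
            SubgroupTestResult(
                "weekend_vs_weekday",
                float(t_stat),
                float(p_value),
                {
                    "weekend_mean": float(np.mean(a)),
                    "weekday_mean": float(np.mean(b)),
                    "n": len(paired),
                },
            )
        )
    else:
        results.append(
            SubgroupTestResult(
                "weekend_vs_weekday",
                None,
                None,
                {
                    "weekend_mean": float(np.mean(a)) if len(a) else float("nan"),
                    "weekday_mean": float(np.mean(b)) if len(b) else float("nan"),
                    "n": len(paired),
                },
                undefined=True,
            )
        )
    return results
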