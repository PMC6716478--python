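"""Event deduplication, 12-hour dosing windows, and capped adherence.

Controller adherence is computed per 12-hour wall-clock window — AM
[00:00, 12:00) and PM [12:00, 24:00) — as ``min(taken, prescribed) /
prescribed``.  The cap guards against medication "dumping" (many actuations
fired at once): extra actuations within a window can never raise adherence
above 1.  Daily adherence averages the windows that have a prescription, and
group adherence is the unweighted mean over all defined participant-days.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from datetime import date
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .episodes import classify_symptom_days, merge_daily_responses
from .types import (
    ActuationEvent,
    AdhemaError,
    ComparisonResult,
    ConfigError,
    DailyRecord,
    EmaReport,
    Medication,
    Regimen,
    Source,
    StudyConfig,
)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def _match_duplicates(
    devices: Sequence[ActuationEvent],
    manuals: Sequence[ActuationEvent],
    tolerance_minutes: float,
) -> list[tuple[int, int]]:
    """One-to-one (device, manual) pairing maximizing the number of pairs
    within tolerance, minimum total |Δt| among those.  Returns index pairs."""
    if not devices or not manuals:
        return []
    dev_t = np.array([e.timestamp.timestamp() for e in devices]) / 60.0
    man_t = np.array([e.timestamp.timestamp() for e in manuals]) / 60.0
    cost = np.abs(dev_t[:, None] - man_t[None, :])
    forbidden = cost > tolerance_minutes
    big = max(1e9, 1e6 * tolerance_minutes)
    cost = np.where(forbidden, big, cost)
    rows, cols = linear_sum_assignment(cost)
    return [(i, j) for i, j in zip(rows, cols) if not forbidden[i, j]]


def deduplicate_events(
    events: Sequence[ActuationEvent],
    tolerance_minutes: float,
    *,
    return_audit: bool = False,
):
    """Drop manual entries that duplicate a device-recorded actuation.

    A manual entry is a duplicate when it can be paired one-to-one with a
    device event of the same participant and medication within
    ``±tolerance_minutes``; pairing maximizes the number of duplicates
    removed and, among such pairings, the total time discrepancy is minimal.
    Device events are never removed.

    With ``return_audit=True`` also returns the list of removed
    ``(manual_event, matched_device_event)`` pairs.
    """
    if tolerance_minutes < 0:
        raise ConfigError("dedup tolerance must be >= 0")
    groups: dict[tuple[str, Medication], dict[Source, list[ActuationEvent]]] = (
        defaultdict(lambda: {Source.DEVICE: [], Source.MANUAL: []})
    )
    for event in events:
        groups[(event.participant_id, event.medication)][event.source].append(event)

    removed: set[int] = set()  # identity of removed manual events
    audit: list[tuple[ActuationEvent, ActuationEvent]] = []
    for group in groups.values():
        devices = group[Source.DEVICE]
        manuals = group[Source.MANUAL]
        for i, j in _match_duplicates(devices, manuals, tolerance_minutes):
            removed.add(id(manuals[j]))
            audit.append((manuals[j], devices[i]))
    kept = sorted(e for e in events if id(e) not in removed)
    if return_audit:
        return kept, audit
    return kept


# ---------------------------------------------------------------------------
# windows and adherence
# ---------------------------------------------------------------------------


def assign_windows(
    events: Iterable[ActuationEvent],
    regimen: Regimen,
) -> tuple[dict[date, list[int]], list[ActuationEvent]]:
    """Bin controller actuations into per-day (AM, PM) counts.

    AM is [00:00, 12:00), PM is [12:00, 24:00) local time.  Controller
    events outside the enrollment window are excluded and returned in the
    discard list; rescue events are ignored here (they never enter
    adherence).
    """
    counts: dict[date, list[int]] = defaultdict(lambda: [0, 0])
    discarded: list[ActuationEvent] = []
    for event in events:
        if event.medication is not Medication.CONTROLLER:
            continue
        day = event.timestamp.date()
        if not regimen.in_range(day):
            discarded.append(event)
            continue
        window = 0 if event.timestamp.hour < 12 else 1
        counts[day][window] += 1
    return dict(counts), discarded


def window_adherence(taken: int, prescribed: int) -> Optional[float]:
    """Capped window adherence; ``None`` when nothing is prescribed."""
    if taken < 0 or prescribed < 0:
        raise ValueError("dose counts must be non-negative")
    if prescribed == 0:
        return None
    return min(taken, prescribed) / prescribed


def daily_adherence(record: DailyRecord, regimen: Regimen) -> Optional[float]:
    """Mean of the defined window adherences for one participant-day."""
    return _daily_adherence(record.am_taken, record.pm_taken, regimen)


def _daily_adherence(am_taken: int, pm_taken: int, regimen: Regimen) -> Optional[float]:
    values = [
        adh
        for adh in (
            window_adherence(am_taken, regimen.am_doses),
            window_adherence(pm_taken, regimen.pm_doses),
        )
        if adh is not None
    ]
    if not values:
        return None
    return statistics.fmean(values)


def group_adherence(records: Iterable[DailyRecord]) -> float:
    """Unweighted mean of all defined participant-day daily adherences."""
    values = [r.daily_adherence for r in records if r.daily_adherence is not None]
    if not values:
        raise AdhemaError("no participant-day with defined daily adherence")
    return statistics.fmean(values)


# ---------------------------------------------------------------------------
# daily record assembly
# ---------------------------------------------------------------------------


def build_daily_records(
    events: Sequence[ActuationEvent],
    reports: Sequence[EmaReport],
    regimen: Regimen,
    config: Optional[StudyConfig] = None,
) -> list[DailyRecord]:
    """Assemble one :class:`DailyRecord` per study day for one participant.

    ``events`` must already be deduplicated.  Same-day reports are merged by
    per-item maximum; a day's symptom flag is ``None`` without a report.
    """
    config = (config or StudyConfig()).validate()
    own_events = [e for e in events if e.participant_id == regimen.participant_id]
    own_reports = [r for r in reports if r.participant_id == regimen.participant_id]
    counts, _ = assign_windows(own_events, regimen)

    any_event_days = {
        e.timestamp.date() for e in own_events if regimen.in_range(e.timestamp.date())
    }
    merged = merge_daily_responses(own_reports)
    flags = classify_symptom_days(own_reports, config)

    records: list[DailyRecord] = []
    for study_day in range(regimen.n_days):
        day = regimen.date_of(study_day)
        am_taken, pm_taken = counts.get(day, (0, 0))
        has_ema = day in merged
        records.append(
            DailyRecord(
                participant_id=regimen.participant_id,
                study_day=study_day,
                date=day,
                am_taken=am_taken,
                pm_taken=pm_taken,
                am_adherence=window_adherence(am_taken, regimen.am_doses),
                pm_adherence=window_adherence(pm_taken, regimen.pm_doses),
                daily_adherence=_daily_adherence(am_taken, pm_taken, regimen),
                has_ema=has_ema,
                has_any_data=has_ema or day in any_event_days,
                symptom_day=flags.get(day),
                responses=dict(merged.get(day, {})),
            )
        )
    return records


def build_cohort_records(
    events: Sequence[ActuationEvent],
    reports: Sequence[EmaReport],
    regimens: Sequence[Regimen],
    config: Optional[StudyConfig] = None,
    *,
    return_audit: bool = False,
):
    """Deduplicate and assemble daily records for a whole cohort."""
    config = (config or StudyConfig()).validate()
    deduped, audit = deduplicate_events(
        events, config.dedup_tolerance_minutes, return_audit=True
    )
    records: list[DailyRecord] = []
    for regimen in regimens:
        records.extend(build_daily_records(deduped, reports, regimen, config))
    if return_audit:
        return records, audit
    return records


# ---------------------------------------------------------------------------
# non-report vs non-symptom-report comparison
# ---------------------------------------------------------------------------


def nonreport_vs_nonsymptom_comparison(
    records: Iterable[DailyRecord],
) -> ComparisonResult:
    """Compare mean adherence on non-symptom-report days vs non-report days.

    Partitions participant-days with defined adherence into days carrying an
    EMA report with no asthma symptoms, and days with no report at all, and
    applies a two-sample Welch t-test.  A systematically lower non-report
    mean is the signature of informative (adherence-linked) missingness.
    """
    nonsymptom: list[float] = []
    nonreport: list[float] = []
    for rec in records:
        if rec.daily_adherence is None:
            continue
        if rec.has_ema and rec.symptom_day is False:
            nonsymptom.append(rec.daily_adherence)
        elif not rec.has_ema:
            nonreport.append(rec.daily_adherence)
    if len(nonsymptom) < 2 or len(nonreport) < 2:
        return ComparisonResult(
            nonsymptom_mean=statistics.fmean(nonsymptom) if nonsymptom else None,
            nonreport_mean=statistics.fmean(nonreport) if nonreport else None,
            n_nonsymptom=len(nonsymptom),
            n_nonreport=len(nonreport),
            t_stat=None,
            p_value=None,
            undefined=True,
        )
    t_stat, p_value = stats.ttest_ind(nonsymptom, nonreport, equal_var=False)
    undefined = not np.isfinite(t_stat)
    return ComparisonResult(
        nonsymptom_mean=statistics.fmean(nonsymptom),
        nonreport_mean=statistics.fmean(nonreport),
        n_nonsymptom=len(nonsymptom),
        n_nonreport=len(nonreport),
        t_stat=float(t_stat) if not undefined else None,
        p_value=float(p_value) if not undefined else None,
        undefined=undefined,
    )
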