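"""Independent brute-force oracles used to cross-check the implementation.

Each oracle enumerates its definition directly and shares no code with the
module it checks.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from adhema.types import ActuationEvent, Medication, Regimen, Source


def episode_starts_brute(flags: Mapping[int, bool], min_day: int = 7) -> list[int]:
    """Episode starts, straight from the two-criterion definition.

    A symptomatic report day d starts an episode iff d >= min_day, some
    report precedes d, and a symptom-free report lies strictly between the
    most recent prior symptomatic report (or enrollment) and d.
    """
    days = sorted(flags)
    starts = []
    for d in days:
        if not flags[d] or d < min_day:
            continue
        prior = [e for e in days if e < d]
        if not prior:
            continue
        prior_symptomatic = [e for e in prior if flags[e]]
        cutoff = max(prior_symptomatic) if prior_symptomatic else -1
        if any(not flags[e] for e in prior if e > cutoff):
            starts.append(d)
    return starts


def initial_exacerbation_end_brute(
    flags: Mapping[int, bool], min_day: int = 7
) -> Optional[int]:
    """Last day of the enrollment-contiguous symptom run, if one exists."""
    days = sorted(flags)
    if not days or not flags[days[0]] or days[0] >= min_day:
        return None
    end = None
    for d in days:
        if flags[d]:
            end = d
        else:
            break
    return end


def best_duplicate_matching(
    devices: Sequence[ActuationEvent],
    manuals: Sequence[ActuationEvent],
    tolerance_minutes: float,
) -> tuple[int, float]:
    """Exhaustive optimal one-to-one matching over all pairings.

    Returns (max number of within-tolerance pairs, min total |dt| minutes
    among maximum pairings).
    """
    best = [-1, float("inf")]

    def recurse(i: int, used: frozenset, count: int, cost: float) -> None:
        if i == len(manuals):
            if count > best[0] or (count == best[0] and cost < best[1]):
                best[0], best[1] = count, cost
            return
        recurse(i + 1, used, count, cost)
        for j, dev in enumerate(devices):
            if j in used:
                continue
            dt = abs(
                (manuals[i].timestamp - dev.timestamp).total_seconds()
            ) / 60.0
            if dt <= tolerance_minutes:
                recurse(i + 1, used | {j}, count + 1, cost + dt)

    recurse(0, frozenset(), 0, 0.0)
    return best[0], best[1] if best[0] > 0 else 0.0


def dedup_oracle(
    events: Sequence[ActuationEvent], tolerance_minutes: float
) -> tuple[int, float]:
    """Optimal (n_removed, total |dt|) over the whole event set."""
    total_pairs, total_cost = 0, 0.0
    keys = sorted({(e.participant_id, e.medication) for e in events},
                  key=lambda k: (k[0], k[1].value))
    for pid, med in keys:
        devices = [
            e
            for e in events
            if e.participant_id == pid
            and e.medication == med
            and e.source is Source.DEVICE
        ]
        manuals = [
            e
            for e in events
            if e.participant_id == pid
            and e.medication == med
            and e.source is Source.MANUAL
        ]
        n, c = best_duplicate_matching(devices, manuals, tolerance_minutes)
        total_pairs += n
        total_cost += c
    return total_pairs, total_cost


def naive_window_counts(
    events: Sequence[ActuationEvent], regimen: Regimen
) -> dict:
    """Per-day (am, pm) controller counts by direct re-scan."""
    counts: dict = {}
    for e in events:
        if e.participant_id != regimen.participant_id:
            continue
        if e.medication is not Medication.CONTROLLER:
            continue
        day = e.timestamp.date()
        if day < regimen.enrollment_date or day > regimen.end_date:
            continue
        am, pm = counts.get(day, (0, 0))
        if e.timestamp.hour < 12:
            am += 1
        else:
            pm += 1
        counts[day] = (am, pm)
    return counts


def naive_daily_adherence(
    am_taken: int, pm_taken: int, regimen: Regimen
) -> Optional[float]:
    """Daily adherence by direct recount: mean of capped window fractions."""
    parts = []
    if regimen.am_doses > 0:
        parts.append(min(am_taken, regimen.am_doses) / regimen.am_doses)
    if regimen.pm_doses > 0:
        parts.append(min(pm_taken, regimen.pm_doses) / regimen.pm_doses)
    if not parts:
        return None
    return sum(parts) / len(parts)
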