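"""Readers and writers for the study interchange tables.

All tables are comma-separated UTF-8 with a header row and ISO-8601
timestamps in local civil time.  Validation is total: every input row is
either accepted or produces a :class:`~adhema.types.RowError` carrying its
line number; readers either raise a :class:`~adhema.types.ValidationError`
listing every bad row (default) or, with ``collect_errors=True``, return the
accepted records together with the error list.
"""

from __future__ import annotations

import csv
import json
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence, Union

from .types import (
    EMA_ITEMS,
    LIKERT_CODE_BY_LABEL,
    ActuationEvent,
    DailyRecord,
    EmaReport,
    FormatError,
    Medication,
    Regimen,
    RowError,
    Source,
    StudyConfig,
    ValidationError,
)

PathLike = Union[str, Path]

EVENT_COLUMNS = ("participant_id", "timestamp", "medication", "source")
EMA_COLUMNS = ("participant_id", "timestamp") + EMA_ITEMS
REGIMEN_COLUMNS = (
    "participant_id",
    "enrollment_date",
    "end_date",
    "am_doses",
    "pm_doses",
)
DAILY_COLUMNS = (
    "participant_id",
    "study_day",
    "date",
    "am_taken",
    "pm_taken",
    "am_adherence",
    "pm_adherence",
    "daily_adherence",
    "has_ema",
    "has_any_data",
    "symptom_day",
) + EMA_ITEMS


def _open_reader(path: PathLike, required: Sequence[str]) -> csv.DictReader:
    handle = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    header = reader.fieldnames or []
    for column in required:
        if column not in header:
            handle.close()
            raise FormatError(f"{path}: missing required column {column!r}")
    return reader


def _parse_timestamp(value: str) -> datetime:
    return datetime.fromisoformat(value.strip())


def _parse_likert(value: str) -> Optional[int]:
    """Accept integer codes 0-3 or the four anchor labels; blank → missing."""
    text = value.strip()
    if not text:
        return None
    lowered = text.lower()
    if lowered in LIKERT_CODE_BY_LABEL:
        return LIKERT_CODE_BY_LABEL[lowered]
    code = int(text)  # may raise ValueError
    if code not in (0, 1, 2, 3):
        raise ValueError(f"Likert code {code} outside 0-3")
    return code


def read_events(
    path: PathLike,
    config: Optional[StudyConfig] = None,
    *,
    collect_errors: bool = False,
):
    """Read inhaler actuation events, sorted by (participant, timestamp)."""
    reader = _open_reader(path, EVENT_COLUMNS)
    events: list[ActuationEvent] = []
    errors: list[RowError] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            event = ActuationEvent(
                participant_id=row["participant_id"].strip(),
                timestamp=_parse_timestamp(row["timestamp"]),
                medication=Medication(row["medication"].strip().lower()),
                source=Source(row["source"].strip().lower()),
            )
            if not event.participant_id:
                raise ValueError("empty participant_id")
        except (ValueError, KeyError) as exc:
            errors.append(RowError(lineno, str(exc)))
            continue
        events.append(event)
    events.sort()
    if collect_errors:
        return events, errors
    if errors:
        raise ValidationError(errors)
    return events


def read_ema(
    path: PathLike,
    config: Optional[StudyConfig] = None,
    *,
    collect_errors: bool = False,
):
    """Read EMA reports; Likert cells may be codes 0-3 or text labels."""
    reader = _open_reader(path, EMA_COLUMNS)
    reports: list[EmaReport] = []
    errors: list[RowError] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            responses: dict[str, int] = {}
            for item in EMA_ITEMS:
                level = _parse_likert(row.get(item) or "")
                if level is not None:
                    responses[item] = level
            report = EmaReport(
                participant_id=row["participant_id"].strip(),
                timestamp=_parse_timestamp(row["timestamp"]),
                responses=responses,
            )
            if not report.participant_id:
                raise ValueError("empty participant_id")
        except (ValueError, KeyError) as exc:
            errors.append(RowError(lineno, str(exc)))
            continue
        reports.append(report)
    reports.sort(key=lambda r: (r.participant_id, r.timestamp))
    if collect_errors:
        return reports, errors
    if errors:
        raise ValidationError(errors)
    return reports


def read_regimen(path: PathLike):
    """Read the per-participant regimen/enrollment table (one row each)."""
    reader = _open_reader(path, REGIMEN_COLUMNS)
    regimens: list[Regimen] = []
    errors: list[RowError] = []
    seen: set[str] = set()
    for lineno, row in enumerate(reader, start=2):
        try:
            pid = row["participant_id"].strip()
            if not pid:
                raise ValueError("empty participant_id")
            if pid in seen:
                raise ValueError(f"duplicate participant_id {pid!r}")
            regimen = Regimen(
                participant_id=pid,
                enrollment_date=date.fromisoformat(row["enrollment_date"].strip()),
                end_date=date.fromisoformat(row["end_date"].strip()),
                am_doses=int(row["am_doses"]),
                pm_doses=int(row["pm_doses"]),
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(lineno, str(exc)))
            continue
        seen.add(pid)
        regimens.append(regimen)
    if errors:
        raise ValidationError(errors)
    return regimens


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_events(events: Sequence[ActuationEvent], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow(
                [e.participant_id, e.timestamp.isoformat(), e.medication.value, e.source.value]
            )


def write_ema(reports: Sequence[EmaReport], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(EMA_COLUMNS)
        for r in reports:
            row = [r.participant_id, r.timestamp.isoformat()]
            row += ["" if item not in r.responses else r.responses[item] for item in EMA_ITEMS]
            writer.writerow(row)


def write_regimen(regimens: Sequence[Regimen], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(REGIMEN_COLUMNS)
        for g in regimens:
            writer.writerow(
                [
                    g.participant_id,
                    g.enrollment_date.isoformat(),
                    g.end_date.isoformat(),
                    g.am_doses,
                    g.pm_doses,
                ]
            )


def _fmt_opt_float(value: Optional[float]) -> str:
    return "" if value is None else repr(float(value))


def _fmt_opt_bool(value: Optional[bool]) -> str:
    if value is None:
        return ""
    return "true" if value else "false"


def write_daily_table(records: Sequence[DailyRecord], path: PathLike) -> None:
    """Write participant-day records; ``read_daily_table`` round-trips them."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(DAILY_COLUMNS)
        for rec in records:
            row = [
                rec.participant_id,
                rec.study_day,
                rec.date.isoformat(),
                rec.am_taken,
                rec.pm_taken,
                _fmt_opt_float(rec.am_adherence),
                _fmt_opt_float(rec.pm_adherence),
                _fmt_opt_float(rec.daily_adherence),
                _fmt_opt_bool(rec.has_ema),
                _fmt_opt_bool(rec.has_any_data),
                _fmt_opt_bool(rec.symptom_day),
            ]
            row += [
                "" if item not in rec.responses else rec.responses[item]
                for item in EMA_ITEMS
            ]
            writer.writerow(row)


def read_daily_table(path: PathLike) -> list[DailyRecord]:
    reader = _open_reader(path, DAILY_COLUMNS)
    records: list[DailyRecord] = []
    errors: list[RowError] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            responses = {}
            for item in EMA_ITEMS:
                cell = (row.get(item) or "").strip()
                if cell:
                    responses[item] = int(cell)
            records.append(
                DailyRecord(
                    participant_id=row["participant_id"].strip(),
                    study_day=int(row["study_day"]),
                    date=date.fromisoformat(row["date"].strip()),
                    am_taken=int(row["am_taken"]),
                    pm_taken=int(row["pm_taken"]),
                    am_adherence=_opt_float(row["am_adherence"]),
                    pm_adherence=_opt_float(row["pm_adherence"]),
                    daily_adherence=_opt_float(row["daily_adherence"]),
                    has_ema=_opt_bool(row["has_ema"]) or False,
                    has_any_data=_opt_bool(row["has_any_data"]) or False,
                    symptom_day=_opt_bool(row["symptom_day"]),
                    responses=responses,
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(lineno, str(exc)))
    if errors:
        raise ValidationError(errors)
    return records


def _opt_float(value: str) -> Optional[float]:
    text = value.strip()
    return None if not text else float(text)


def _opt_bool(value: str) -> Optional[bool]:
    text = value.strip().lower()
    if not text:
        return None
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise ValueError(f"bad boolean cell {value!r}")


def write_json(obj, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")
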