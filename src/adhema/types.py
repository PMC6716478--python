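"""Core domain types for smartphone asthma-monitoring analyses.

The analysis unit is a cohort of youth with high-risk asthma followed for
roughly two months, with three raw data streams per participant:

* timestamped inhaler actuations from Bluetooth inhaler caps, supplemented by
  manual in-app entries (``ActuationEvent``);
* daily ecological momentary assessments (EMA) — eight 4-point Likert items
  covering asthma symptoms (cough, wheeze, chest tightness) and mood
  (stressed, angry, bored, happy, relaxed) (``EmaReport``);
* the prescribed twice-daily controller regimen and enrollment window
  (``Regimen``).

Derived per participant-day quantities live in ``DailyRecord``; detected
symptom episodes in ``EpisodeResult``; mixed-model output in
``ModelEstimate``.  All containers are plain dataclasses so that they
round-trip losslessly through the CSV/JSON interchange formats in
:mod:`adhema.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from enum import Enum
from typing import Mapping, Optional, Sequence

#: The eight EMA items, in questionnaire order.
EMA_ITEMS: tuple[str, ...] = (
    "cough",
    "wheeze",
    "chest_tight",
    "stressed",
    "angry",
    "bored",
    "happy",
    "relaxed",
)

#: Items whose report constitutes an asthma symptom.
SYMPTOM_ITEMS: tuple[str, ...] = ("cough", "wheeze", "chest_tight")

#: Mood / contextual items.
MOOD_ITEMS: tuple[str, ...] = ("stressed", "angry", "bored", "happy", "relaxed")

#: Likert anchor labels, index = numeric code.
LIKERT_LABELS: tuple[str, ...] = ("Not at all", "A little", "A lot", "Extremely")

LIKERT_CODE_BY_LABEL: dict[str, int] = {
    label.lower(): code for code, label in enumerate(LIKERT_LABELS)
}

#: Reference level per item for the association models.  Symptom and
#: negative-mood items are referenced to "Not at all" (0); the positively
#: worded happy/relaxed items to "Extremely" (3), so that every effect reads
#: as a departure from the untroubled state.
REFERENCE_LEVELS: dict[str, int] = {
    "cough": 0,
    "wheeze": 0,
    "chest_tight": 0,
    "stressed": 0,
    "angry": 0,
    "bored": 0,
    "happy": 3,
    "relaxed": 3,
    "any_symptom": 0,
}


class Medication(str, Enum):
    """Medication class of an inhaler actuation."""

    CONTROLLER = "controller"
    RESCUE = "rescue"


class Source(str, Enum):
    """Channel an actuation record arrived through."""

    DEVICE = "device"
    MANUAL = "manual"


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class AdhemaError(Exception):
    """Base class for all package errors."""


class ConfigError(AdhemaError):
    """Invalid analysis or simulation configuration."""


class FormatError(AdhemaError):
    """A file is structurally unusable (e.g. a required column is absent)."""


@dataclass(frozen=True)
class RowError:
    """A located, row-level validation failure."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"line {self.line}: {self.message}"


class ValidationError(AdhemaError):
    """One or more rows failed validation; every failure is listed."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        super().__init__(
            "; ".join(str(e) for e in self.errors) or "validation failed"
        )


class ModelFitError(AdhemaError):
    """A mixed-model fit failed or is unidentifiable; names the item."""

    def __init__(self, item: str, reason: str):
        self.item = item
        self.reason = reason
        super().__init__(f"model for {item!r}: {reason}")


# ---------------------------------------------------------------------------
# raw-stream records
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class ActuationEvent:
    """A single timestamped inhaler use.

    Timestamps are the participant's local civil time; the 12-hour adherence
    windows are defined by wall clock, so no timezone arithmetic is applied
    anywhere in the package.
    """

    participant_id: str
    timestamp: datetime
    medication: Medication
    source: Source


@dataclass(frozen=True)
class EmaReport:
    """One EMA questionnaire instance.

    ``responses`` maps item name to Likert code 0..3; items a participant
    skipped are simply absent.
    """

    participant_id: str
    timestamp: datetime
    responses: Mapping[str, int]

    def __post_init__(self) -> None:
        for item, level in self.responses.items():
            if item not in EMA_ITEMS:
                raise ValueError(f"unknown EMA item {item!r}")
            if level not in (0, 1, 2, 3):
                raise ValueError(f"{item}={level!r} outside Likert range 0-3")


@dataclass(frozen=True)
class Regimen:
    """Prescribed controller regimen and enrollment window for a participant.

    ``am_doses`` / ``pm_doses`` are the controller doses prescribed in the
    [00:00, 12:00) and [12:00, 24:00) windows respectively.
    """

    participant_id: str
    enrollment_date: date
    end_date: date
    am_doses: int
    pm_doses: int

    def __post_init__(self) -> None:
        if self.end_date < self.enrollment_date:
            raise ValueError(
                f"{self.participant_id}: end_date precedes enrollment_date"
            )
        if self.am_doses < 0 or self.pm_doses < 0:
            raise ValueError(f"{self.participant_id}: negative dose count")
        if self.am_doses + self.pm_doses < 1:
            raise ValueError(
                f"{self.participant_id}: no controller doses prescribed "
                "(every enrolled participant is on a controller medication)"
            )

    @property
    def n_days(self) -> int:
        """Number of study days, enrollment day (study day 0) included."""
        return (self.end_date - self.enrollment_date).days + 1

    def study_day(self, when: date) -> int:
        return (when - self.enrollment_date).days

    def date_of(self, study_day: int) -> date:
        return self.enrollment_date + timedelta(days=study_day)

    def in_range(self, when: date) -> bool:
        return self.enrollment_date <= when <= self.end_date


@dataclass
class StudyConfig:
    """Tunable analysis parameters.

    dedup_tolerance_minutes
        Maximum |Δt| for a manual entry to be treated as a duplicate of a
        device-recorded actuation (default 60).
    symptom_threshold
        Minimum Likert level on any symptom item for a report to flag an
        asthma symptom day (default 1, "A little").
    initial_exacerbation_days
        Days post-enrollment a symptom report must reach before it can start
        a *new* symptom episode (default 7).
    """

    dedup_tolerance_minutes: float = 60.0
    symptom_threshold: int = 1
    initial_exacerbation_days: int = 7
    verbosity: int = 0

    def validate(self) -> "StudyConfig":
        if self.dedup_tolerance_minutes < 0:
            raise ConfigError("dedup_tolerance_minutes must be >= 0")
        if self.symptom_threshold not in (1, 2, 3):
            raise ConfigError("symptom_threshold must be 1, 2 or 3")
        if self.initial_exacerbation_days < 0:
            raise ConfigError("initial_exacerbation_days must be >= 0")
        return self


# ---------------------------------------------------------------------------
# derived records
# ---------------------------------------------------------------------------


@dataclass
class DailyRecord:
    """The participant-day analysis unit.

    Adherence fields are ``None`` where undefined (no doses prescribed in the
    corresponding window); ``symptom_day`` is ``None`` when no EMA report was
    received that day — an unreported day is never coerced to "no symptoms"
    outside the explicit imputation sensitivity analysis.
    """

    participant_id: str
    study_day: int
    date: date
    am_taken: int = 0
    pm_taken: int = 0
    am_adherence: Optional[float] = None
    pm_adherence: Optional[float] = None
    daily_adherence: Optional[float] = None
    has_ema: bool = False
    has_any_data: bool = False
    symptom_day: Optional[bool] = None
    responses: dict[str, int] = field(default_factory=dict)


@dataclass
class EpisodeResult:
    """Detected new symptom episodes for one participant.

    ``initial_exacerbation_end`` is the last study day of the
    enrollment-contiguous symptom run (``None`` if the participant's first
    report was symptom-free or no report exists).  ``indeterminate_onset``
    flags the case where the first-ever report was symptomatic at or after
    the episode threshold day, which cannot be adjudicated as new or ongoing.
    """

    participant_id: str
    initial_exacerbation_end: Optional[int] = None
    episode_start_days: list[int] = field(default_factory=list)
    indeterminate_onset: bool = False

    @property
    def episode_count(self) -> int:
        return len(self.episode_start_days)


@dataclass
class RedesignComparison:
    """Pre- vs post-redesign acquisition comparison (Welch t-test)."""

    metric: str
    pre_mean: float
    post_mean: float
    n_pre: int
    n_post: int
    t_stat: Optional[float]
    p_value: Optional[float]
    undefined: bool = False


@dataclass
class AcquisitionSummary:
    """Cohort data-acquisition metrics.

    Fractions are over participant-days within each participant's enrollment
    window; a day counts as "any data" when it carries at least one actuation
    record or an EMA report.
    """

    total_days: int
    any_data_days: int
    ema_days: int
    any_data_fraction: float
    ema_fraction: float
    per_participant: dict[str, dict[str, float]] = field(default_factory=dict)
    redesign: list[RedesignComparison] = field(default_factory=list)


@dataclass
class ComparisonResult:
    """Mean adherence on non-symptom-report days vs non-report days."""

    nonsymptom_mean: Optional[float]
    nonreport_mean: Optional[float]
    n_nonsymptom: int
    n_nonreport: int
    t_stat: Optional[float]
    p_value: Optional[float]
    undefined: bool = False


@dataclass
class SubgroupTestResult:
    """One EMA-reporting-frequency subgroup test."""

    name: str
    statistic: Optional[float]
    p_value: Optional[float]
    detail: dict[str, float] = field(default_factory=dict)
    undefined: bool = False


@dataclass
class ModelEstimate:
    """One fitted fixed effect from the daily-adherence mixed model.

    ``effect`` is the change in daily adherence, in percentage points,
    relative to the item's reference level.  Reference rows carry
    ``is_reference=True`` and effect 0 by construction; levels never observed
    in the data carry ``na_flag=True`` and no estimate.
    """

    item: str
    level: int
    reference_level: int
    effect: Optional[float] = None
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    n_days: int = 0
    n_participants: int = 0
    re_var: Optional[float] = None
    resid_var: Optional[float] = None
    na_flag: bool = False
    is_reference: bool = False
    mode: str = "report_days_only"


@dataclass
class SensitivityComparison:
    """Report-days-only vs imputed-non-report-days estimate comparison."""

    item: str
    level: int
    report: ModelEstimate
    imputed: ModelEstimate
    difference: Optional[float]
    report_ci_width: Optional[float]
    imputed_ci_width: Optional[float]
    imputed_narrower: Optional[bool]
    sign_flip: bool = False
    shift_exceeds_se: bool = False

    @property
    def flagged(self) -> bool:
        return self.sign_flip or self.shift_exceeds_se
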