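"""Synthetic smartphone asthma-monitoring cohorts.

The generator emulates the statistical structure the analysis assumes: a
small cohort on twice-daily controller regimens with low mean adherence
(per-dose Bernoulli take probability ~0.30) and substantial
between-participant heterogeneity (logit-normal random effect), episodic
symptom runs (hazard-onset, geometric duration, optional
enrollment-contiguous initial exacerbation), daily Likert item responses,
EMA reporting on a minority of days with optionally adherence-linked
(informative) missingness, device/manual duplicate event pairs with
timestamp jitter, and rescue use concentrated on symptom days.

Every latent quantity — participant random effects, daily take
probabilities, the symptom calendar and which episodes the detection rule
could recover — is recorded in a truth block so that each pipeline stage can
be tested for recovery of known ground truth.  A fixed seed reproduces the
full output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import io
from .episodes import detect_new_episodes
from .types import (
    EMA_ITEMS,
    MOOD_ITEMS,
    REFERENCE_LEVELS,
    SYMPTOM_ITEMS,
    ActuationEvent,
    ConfigError,
    EmaReport,
    Medication,
    Regimen,
    Source,
    StudyConfig,
)

_DEFAULT_SYMPTOM_LEVEL_PROBS: dict[str, tuple[float, ...]] = {
    # level distribution on symptomatic days; wheeze/chest tightness rarely
    # exceed "A little" in this population
    "cough": (0.30, 0.55, 0.15, 0.00),
    "wheeze": (0.60, 0.40, 0.00, 0.00),
    "chest_tight": (0.60, 0.40, 0.00, 0.00),
}

_DEFAULT_MOOD_LEVEL_PROBS: dict[str, tuple[float, ...]] = {
    "stressed": (0.89, 0.08, 0.02, 0.01),
    "angry": (0.90, 0.07, 0.02, 0.01),
    "bored": (0.48, 0.30, 0.14, 0.08),
    "happy": (0.08, 0.16, 0.22, 0.54),
    "relaxed": (0.06, 0.14, 0.20, 0.60),
}


@dataclass
class SimulationConfig:
    """Cohort-generator parameters; defaults reproduce the study conditions
    (14 participants, 60 days, twice-daily controller, mean per-dose take
    probability 0.30, EMA on ~20% of days)."""

    n_participants: int = 14
    study_days: int = 60
    am_doses: int = 1
    pm_doses: int = 1
    enrollment_date: date = date(2015, 8, 1)
    base_take_prob: float = 0.30
    participant_logit_sd: float = 1.0
    #: optional day-level logit jitter on the take probability; > 0 creates
    #: within-participant day-to-day adherence variation (and, combined with
    #: ``missingness_coef``, day-level informative missingness)
    day_logit_sd: float = 0.0
    #: (item, level) → additive shift in take probability on exposure days
    item_effects: Mapping[tuple[str, int], float] = field(default_factory=dict)
    initial_exacerbation_prob: float = 0.5
    initial_exacerbation_mean_days: float = 3.0
    episode_hazard: float = 0.02
    episode_mean_days: float = 3.0
    ema_prob: float = 0.20
    #: report-probability shift per unit shift in that day's take probability
    missingness_coef: float = 0.0
    item_missing_prob: float = 0.02
    manual_only_prob: float = 0.05
    duplicate_prob: float = 0.10
    duplicate_jitter_sd_minutes: float = 5.0
    rescue_prob_symptom_day: float = 0.30
    rescue_prob_other_day: float = 0.02
    am_dose_hours: tuple[int, int] = (6, 11)
    pm_dose_hours: tuple[int, int] = (18, 23)
    symptom_level_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_SYMPTOM_LEVEL_PROBS)
    )
    mood_level_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_MOOD_LEVEL_PROBS)
    )
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        probs = {
            "base_take_prob": self.base_take_prob,
            "initial_exacerbation_prob": self.initial_exacerbation_prob,
            "episode_hazard": self.episode_hazard,
            "ema_prob": self.ema_prob,
            "item_missing_prob": self.item_missing_prob,
            "manual_only_prob": self.manual_only_prob,
            "duplicate_prob": self.duplicate_prob,
            "rescue_prob_symptom_day": self.rescue_prob_symptom_day,
            "rescue_prob_other_day": self.rescue_prob_other_day,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.n_participants < 1 or self.study_days < 1:
            raise ConfigError("cohort dimensions must be positive")
        if self.episode_mean_days < 1 or self.initial_exacerbation_mean_days < 1:
            raise ConfigError("episode durations must average >= 1 day")
        if self.participant_logit_sd < 0 or self.day_logit_sd < 0:
            raise ConfigError("logit-scale SDs must be >= 0")
        for (item, level) in self.item_effects:
            if item not in EMA_ITEMS or level not in (0, 1, 2, 3):
                raise ConfigError(f"bad item_effects key ({item}, {level})")
        return self


@dataclass
class Cohort:
    """In-memory simulated cohort plus its ground-truth block."""

    events: list[ActuationEvent]
    reports: list[EmaReport]
    regimens: list[Regimen]
    truth: dict


def calibrated_logit_mean(target: float, sd: float) -> float:
    """Logit intercept μ with E[expit(μ + sd·Z)] = target, Z ~ N(0,1).

    Gauss–Hermite quadrature; keeps the population-mean take probability at
    the configured value despite the nonlinearity of the inverse logit.
    """
    if not 0.0 <= target <= 1.0:
        raise ConfigError("base_take_prob must lie in [0, 1]")
    if target in (0.0, 1.0):
        # degenerate boundary: every (or no) dose is taken regardless of sd
        return float(logit(target))
    if sd == 0:
        return float(logit(target))
    nodes, weights = np.polynomial.hermite.hermgauss(41)
    z = np.sqrt(2.0) * nodes
    w = weights / np.sqrt(np.pi)

    def mean_minus_target(mu: float) -> float:
        return float(np.sum(w * expit(mu + sd * z)) - target)

    lo, hi = logit(target) - 6 * sd, logit(target) + 6 * sd
    return float(brentq(mean_minus_target, lo, hi, xtol=1e-12))


def _runs(symptomatic: np.ndarray) -> list[int]:
    """Start days of maximal symptomatic runs."""
    padded = np.concatenate(([False], symptomatic))
    return list(np.flatnonzero(symptomatic & ~padded[:-1]))


def _symptom_calendar(
    rng: np.random.Generator, config: SimulationConfig
) -> np.ndarray:
    days = config.study_days
    symptomatic = np.zeros(days, dtype=bool)
    day = 0
    if rng.random() < config.initial_exacerbation_prob:
        length = int(rng.geometric(1.0 / config.initial_exacerbation_mean_days))
        symptomatic[:length] = True
        day = length
    while day < days:
        if rng.random() < config.episode_hazard:
            duration = int(rng.geometric(1.0 / config.episode_mean_days))
            symptomatic[day : day + duration] = True
            day += duration
        else:
            day += 1
    return symptomatic


def _draw_levels(
    rng: np.random.Generator, probs: Sequence[float], n: int
) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ConfigError(f"level probabilities {probs} must sum to 1")
    return rng.choice(4, size=n, p=p)


def _participant_calendar(cal_rng, config):
    symptomatic = _symptom_calendar(cal_rng, config)
    run_starts = _runs(symptomatic)
    full_flags = {d: bool(symptomatic[d]) for d in range(config.study_days)}
    detectable = detect_new_episodes(full_flags, StudyConfig())
    return symptomatic, run_starts, detectable


def generate_episode_truth(config: SimulationConfig) -> dict[str, dict]:
    """Per-participant symptom calendar and episode ground truth.

    Uses the same per-participant random substreams as
    :func:`generate_cohort`, so the calendars agree with the full cohort
    generated from the same config.
    """
    config = config.validate()
    root = np.random.SeedSequence(config.seed)
    truth: dict[str, dict] = {}
    for i, child in enumerate(root.spawn(config.n_participants)):
        cal_ss, _ = child.spawn(2)
        symptomatic, run_starts, detectable = _participant_calendar(
            np.random.default_rng(cal_ss), config
        )
        truth[f"P{i + 1:02d}"] = {
            "symptom_days": [int(d) for d in np.flatnonzero(symptomatic)],
            "run_starts": [int(d) for d in run_starts],
            "initial_exacerbation_end": detectable.initial_exacerbation_end,
            "episode_starts_full_observation": list(
                detectable.episode_start_days
            ),
        }
    return truth


def generate_cohort(config: Optional[SimulationConfig] = None) -> Cohort:
    """Generate a full synthetic cohort (events, EMA reports, regimens)."""
    config = (config or SimulationConfig()).validate()
    total_sd = float(
        np.hypot(config.participant_logit_sd, config.day_logit_sd)
    )
    mu = calibrated_logit_mean(config.base_take_prob, total_sd)
    root = np.random.SeedSequence(config.seed)
    days = config.study_days
    enroll = config.enrollment_date
    end = enroll + timedelta(days=days - 1)

    events: list[ActuationEvent] = []
    reports: list[EmaReport] = []
    regimens: list[Regimen] = []
    truth: dict = {
        "config": {
            "base_take_prob": config.base_take_prob,
            "participant_logit_sd": config.participant_logit_sd,
            "ema_prob": config.ema_prob,
            "missingness_coef": config.missingness_coef,
            "item_effects": [
                [item, level, delta]
                for (item, level), delta in sorted(config.item_effects.items())
            ],
            "seed": config.seed,
        },
        "participants": {},
    }

    for i, child in enumerate(root.spawn(config.n_participants)):
        pid = f"P{i + 1:02d}"
        cal_ss, rest_ss = child.spawn(2)
        symptomatic, run_starts, detectable = _participant_calendar(
            np.random.default_rng(cal_ss), config
        )
        rng = np.random.default_rng(rest_ss)
        regimens.append(
            Regimen(pid, enroll, end, config.am_doses, config.pm_doses)
        )

        b = float(rng.normal(0.0, config.participant_logit_sd))

        # latent daily item levels (drawn whether or not the day is reported)
        levels: dict[str, np.ndarray] = {}
        for item in SYMPTOM_ITEMS:
            drawn = _draw_levels(rng, config.symptom_level_probs[item], days)
            drawn[~symptomatic] = 0
            levels[item] = drawn
        # symptomatic days must show at least one symptom item
        silent = symptomatic & np.all(
            [levels[item] == 0 for item in SYMPTOM_ITEMS], axis=0
        )
        levels["cough"] = np.where(silent, 1, levels["cough"])
        for item in MOOD_ITEMS:
            levels[item] = _draw_levels(rng, config.mood_level_probs[item], days)

        day_noise = (
            rng.normal(0.0, config.day_logit_sd, size=days)
            if config.day_logit_sd > 0
            else np.zeros(days)
        )
        take_prob = expit(mu + b + day_noise)
        for (item, level), delta in sorted(config.item_effects.items()):
            take_prob = take_prob + delta * (levels[item] == level)
        take_prob = np.clip(take_prob, 0.0, 1.0)

        dates = [enroll + timedelta(days=int(d)) for d in range(days)]

        for window_doses, (h_lo, h_hi) in (
            (config.am_doses, config.am_dose_hours),
            (config.pm_doses, config.pm_dose_hours),
        ):
            for _dose in range(window_doses):
                taken = rng.random(days) < take_prob
                minutes = rng.integers(h_lo * 60, h_hi * 60, size=days)
                manual_only = rng.random(days) < config.manual_only_prob
                duplicate = rng.random(days) < config.duplicate_prob
                jitter = rng.normal(
                    0.0, config.duplicate_jitter_sd_minutes, size=days
                )
                for d in np.flatnonzero(taken):
                    stamp = datetime.combine(dates[d], time(0, 0)) + timedelta(
                        minutes=int(minutes[d])
                    )
                    source = (
                        Source.MANUAL if manual_only[d] else Source.DEVICE
                    )
                    events.append(
                        ActuationEvent(pid, stamp, Medication.CONTROLLER, source)
                    )
                    if source is Source.DEVICE and duplicate[d]:
                        offset = int(round(jitter[d]))
                        dup_minute = min(max(int(minutes[d]) + offset, 0), 1439)
                        events.append(
                            ActuationEvent(
                                pid,
                                datetime.combine(dates[d], time(0, 0))
                                + timedelta(minutes=dup_minute),
                                Medication.CONTROLLER,
                                Source.MANUAL,
                            )
                        )

        rescue_prob = np.where(
            symptomatic,
            config.rescue_prob_symptom_day,
            config.rescue_prob_other_day,
        )
        rescue = rng.random(days) < rescue_prob
        rescue_minutes = rng.integers(0, 1440, size=days)
        for d in np.flatnonzero(rescue):
            events.append(
                ActuationEvent(
                    pid,
                    datetime.combine(dates[d], time(0, 0))
                    + timedelta(minutes=int(rescue_minutes[d])),
                    Medication.RESCUE,
                    Source.DEVICE,
                )
            )

        report_prob = np.clip(
            config.ema_prob
            + config.missingness_coef * (take_prob - config.base_take_prob),
            0.0,
            1.0,
        )
        reported = rng.random(days) < report_prob
        report_minutes = rng.integers(8 * 60, 22 * 60, size=days)
        missing = rng.random((days, len(EMA_ITEMS))) < config.item_missing_prob
        for d in np.flatnonzero(reported):
            responses = {
                item: int(levels[item][d])
                for k, item in enumerate(EMA_ITEMS)
                if not missing[d, k]
            }
            reports.append(
                EmaReport(
                    pid,
                    datetime.combine(dates[d], time(0, 0))
                    + timedelta(minutes=int(report_minutes[d])),
                    responses,
                )
            )

        realized_flags = {
            int(d): bool(symptomatic[d]) for d in np.flatnonzero(reported)
        }
        detected_given_reporting = detect_new_episodes(
            realized_flags, StudyConfig()
        )
        truth["participants"][pid] = {
            "random_effect": b,
            "logit_mu": mu,
            "take_prob": [float(p) for p in take_prob],
            "report_prob": [float(p) for p in report_prob],
            "report_days": [int(d) for d in np.flatnonzero(reported)],
            "symptom_days": [int(d) for d in np.flatnonzero(symptomatic)],
            "run_starts": [int(d) for d in run_starts],
            "initial_exacerbation_end": detectable.initial_exacerbation_end,
            "episode_starts_full_observation": list(
                detectable.episode_start_days
            ),
            "episode_starts_detectable": list(
                detected_given_reporting.episode_start_days
            ),
        }

    events.sort()
    reports.sort(key=lambda r: (r.participant_id, r.timestamp))
    return Cohort(events=events, reports=reports, regimens=regimens, truth=truth)


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write events.csv, ema.csv, regimen.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": outdir / "events.csv",
        "ema": outdir / "ema.csv",
        "regimen": outdir / "regimen.csv",
        "truth": outdir / "truth.json",
    }
    io.write_events(cohort.events, paths["events"])
    io.write_ema(cohort.reports, paths["ema"])
    io.write_regimen(cohort.regimens, paths["regimen"])
    io.write_json(cohort.truth, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Gaussian frame generator for model validation
# ---------------------------------------------------------------------------


def generate_linear_frame(
    n_participants: int = 30,
    n_days: int = 60,
    item: str = "bored",
    level: int = 3,
    effect: float = 20.0,
    exposure_prob: float = 0.15,
    intercept: float = 30.0,
    time_slope: float = 0.0,
    re_sd: float = 10.0,
    resid_sd: float = 25.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a model frame straight from the mixed model's own equation.

    adherence_pct = intercept + time_slope·day + effect·1[exposed]
                    + N(0, re_sd²) per participant + N(0, resid_sd²) noise,
    with exposure days Bernoulli(exposure_prob).  Used to check that the
    fitting machinery recovers a known fixed effect with nominal coverage.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    reference = REFERENCE_LEVELS[item]
    if level == reference:
        raise ConfigError("planted level must differ from the reference level")
    pid = np.repeat([f"S{i + 1:03d}" for i in range(n_participants)], n_days)
    day = np.tile(np.arange(n_days), n_participants)
    exposed = rng.random(n_participants * n_days) < exposure_prob
    b = np.repeat(rng.normal(0.0, re_sd, size=n_participants), n_days)
    eps = rng.normal(0.0, resid_sd, size=n_participants * n_days)
    outcome = intercept + time_slope * day + effect * exposed + b + eps
    frame = pd.DataFrame(
        {
            "participant_id": pid,
            "study_day": day.astype(float),
            "adherence_pct": outcome,
            item: np.where(exposed, level, reference).astype(float),
        }
    )
    frame.attrs["mode"] = "report_days_only"
    frame.attrs["true_effect"] = effect
    return frame
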