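"""End-to-end orchestration: dedup → windows → adherence → symptoms →
episodes → acquisition → association models, plus report rendering.

The :class:`PipelineResult` holds only reproducible summary sections; every
cohort aggregate it reports equals a recomputation from the per-participant
records it summarizes, and a provenance block (config hash, input
checksums) suffices to re-run the pipeline byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from . import adherence as adh
from . import episodes as epi
from . import models as mdl
from .types import (
    AcquisitionSummary,
    ActuationEvent,
    AdhemaError,
    ComparisonResult,
    DailyRecord,
    EmaReport,
    EpisodeResult,
    LIKERT_LABELS,
    ModelEstimate,
    RedesignComparison,
    Regimen,
    SensitivityComparison,
    StudyConfig,
)

_ITEM_QUESTIONS = {
    "cough": "Are you coughing?",
    "wheeze": "Are you wheezing?",
    "chest_tight": "Does your chest feel tight?",
    "stressed": "Are you stressed?",
    "angry": "Are you angry?",
    "bored": "Are you bored?",
    "happy": "Are you happy?",
    "relaxed": "Are you relaxed?",
    "any_symptom": "Any asthma symptom",
}


@dataclass
class PipelineResult:
    """All cohort-level outputs of one pipeline run."""

    acquisition: Optional[AcquisitionSummary]
    group_adherence: Optional[float]
    episodes: list[EpisodeResult]
    episode_total: int
    estimates: list[ModelEstimate]
    sensitivity: list[SensitivityComparison]
    comparison: Optional[ComparisonResult]
    model_errors: dict[str, str]
    provenance: dict
    daily_records: list[DailyRecord] = field(default_factory=list, repr=False)


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    events: Sequence[ActuationEvent],
    reports: Sequence[EmaReport],
    regimens: Sequence[Regimen],
    config: Optional[StudyConfig] = None,
    *,
    modes: Sequence[str] = ("report_days_only",),
    items: Optional[Sequence[str]] = None,
    redesign_groups: Optional[Mapping[str, str]] = None,
) -> PipelineResult:
    """Run every analysis stage in fixed order on validated inputs.

    Model-stage failures degrade gracefully: all other sections are still
    produced and per-item failures are recorded in ``model_errors``.
    """
    config = (config or StudyConfig()).validate()
    for mode in modes:
        if mode not in mdl.MODES:
            raise ValueError(f"unknown mode {mode!r}")

    records, audit = adh.build_cohort_records(
        events, reports, regimens, config, return_audit=True
    )

    try:
        group = adh.group_adherence(records)
    except AdhemaError:
        group = None

    acquisition = epi.acquisition_metrics(records, redesign_groups)
    comparison = adh.nonreport_vs_nonsymptom_comparison(records)

    episodes: list[EpisodeResult] = []
    for regimen in regimens:
        flags = {
            r.study_day: r.symptom_day
            for r in records
            if r.participant_id == regimen.participant_id
            and r.symptom_day is not None
        }
        episodes.append(
            epi.detect_new_episodes(flags, config, regimen.participant_id)
        )
    episode_total = sum(e.episode_count for e in episodes)

    estimates: list[ModelEstimate] = []
    model_errors: dict[str, str] = {}
    by_mode: dict[str, dict[tuple[str, int], ModelEstimate]] = {}
    for mode in modes:
        frame = mdl.build_model_frame(records, mode, config)
        fitted, errors = mdl.fit_all_items(frame, items)
        estimates.extend(fitted)
        for item, reason in errors.items():
            model_errors[f"{item}[{mode}]"] = reason
        by_mode[mode] = {(e.item, e.level): e for e in fitted}

    sensitivity: list[SensitivityComparison] = []
    if "report_days_only" in by_mode and "impute_nonreport" in by_mode:
        for key, rep in by_mode["report_days_only"].items():
            imp = by_mode["impute_nonreport"].get(key)
            if imp is not None and not rep.is_reference and not rep.na_flag:
                sensitivity.append(mdl.sensitivity_compare(rep, imp))

    provenance = {
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
        "n_events_in": len(events),
        "n_events_deduplicated": len(events) - len(audit),
        "n_duplicates_removed": len(audit),
        "n_reports": len(reports),
        "n_participants": len(regimens),
        "n_daily_records": len(records),
        "modes": list(modes),
    }

    return PipelineResult(
        acquisition=acquisition,
        group_adherence=group,
        episodes=episodes,
        episode_total=episode_total,
        estimates=estimates,
        sensitivity=sensitivity,
        comparison=comparison,
        model_errors=model_errors,
        provenance=provenance,
        daily_records=records,
    )


# ---------------------------------------------------------------------------
# serialization / rendering
# ---------------------------------------------------------------------------


def result_to_dict(result: PipelineResult) -> dict:
    """JSON-serializable view of a :class:`PipelineResult` (summary sections
    only; per-day records travel via the daily table, not the report)."""

    def est(e: ModelEstimate) -> dict:
        return dataclasses.asdict(e)

    return {
        "acquisition": dataclasses.asdict(result.acquisition)
        if result.acquisition
        else None,
        "group_adherence": result.group_adherence,
        "episodes": [dataclasses.asdict(e) for e in result.episodes],
        "episode_total": result.episode_total,
        "estimates": [est(e) for e in result.estimates],
        "sensitivity": [
            {
                "item": s.item,
                "level": s.level,
                "report": est(s.report),
                "imputed": est(s.imputed),
                "difference": s.difference,
                "report_ci_width": s.report_ci_width,
                "imputed_ci_width": s.imputed_ci_width,
                "imputed_narrower": s.imputed_narrower,
                "sign_flip": s.sign_flip,
                "shift_exceeds_se": s.shift_exceeds_se,
                "flagged": s.flagged,
            }
            for s in result.sensitivity
        ],
        "comparison": dataclasses.asdict(result.comparison)
        if result.comparison
        else None,
        "model_errors": dict(result.model_errors),
        "provenance": result.provenance,
    }


def result_from_dict(payload: Mapping) -> PipelineResult:
    """Rebuild a :class:`PipelineResult` from its JSON form."""

    def est(d: Mapping) -> ModelEstimate:
        return ModelEstimate(**d)

    acq = None
    if payload.get("acquisition"):
        a = dict(payload["acquisition"])
        a["redesign"] = [RedesignComparison(**r) for r in a.get("redesign", [])]
        acq = AcquisitionSummary(**a)
    comparison = (
        ComparisonResult(**payload["comparison"])
        if payload.get("comparison")
        else None
    )
    sensitivity = []
    for s in payload.get("sensitivity", []):
        sensitivity.append(
            SensitivityComparison(
                item=s["item"],
                level=s["level"],
                report=est(s["report"]),
                imputed=est(s["imputed"]),
                difference=s["difference"],
                report_ci_width=s["report_ci_width"],
                imputed_ci_width=s["imputed_ci_width"],
                imputed_narrower=s["imputed_narrower"],
                sign_flip=s["sign_flip"],
                shift_exceeds_se=s["shift_exceeds_se"],
            )
        )
    return PipelineResult(
        acquisition=acq,
        group_adherence=payload.get("group_adherence"),
        episodes=[EpisodeResult(**e) for e in payload.get("episodes", [])],
        episode_total=payload.get("episode_total", 0),
        estimates=[est(e) for e in payload.get("estimates", [])],
        sensitivity=sensitivity,
        comparison=comparison,
        model_errors=dict(payload.get("model_errors", {})),
        provenance=dict(payload.get("provenance", {})),
    )


def _fmt(value: Optional[float], digits: int = 1) -> str:
    return "—" if value is None else f"{value:.{digits}f}"


def _estimate_cell(e: ModelEstimate) -> str:
    if e.na_flag:
        return "N/A"
    if e.is_reference:
        return "Reference"
    return (
        f"{e.effect:+.1f}% ({e.ci_low:.1f}% to {e.ci_high:.1f}%)"
    )


def render_report(result: PipelineResult, format: str = "json") -> str:
    """Render a pipeline result as canonical JSON or a markdown summary."""
    if format == "json":
        return json.dumps(result_to_dict(result), indent=2, sort_keys=True) + "\n"
    if format != "markdown":
        raise ValueError("format must be 'json' or 'markdown'")

    lines: list[str] = ["# Cohort monitoring report", ""]
    if result.group_adherence is not None:
        lines.append(
            f"- Group controller adherence: "
            f"{result.group_adherence * 100:.1f}%"
        )
    else:
        lines.append("- Group controller adherence: undefined (no dosed days)")
    if result.acquisition:
        a = result.acquisition
        lines.append(
            f"- Days with any data: {a.any_data_days}/{a.total_days} "
            f"({a.any_data_fraction * 100:.0f}%)"
        )
        lines.append(
            f"- Days with EMA: {a.ema_days}/{a.total_days} "
            f"({a.ema_fraction * 100:.0f}%)"
        )
    lines.append(f"- New asthma symptom episodes: {result.episode_total}")
    if result.comparison and not result.comparison.undefined:
        c = result.comparison
        lines.append(
            "- Adherence, non-symptom-report vs non-report days: "
            f"{c.nonsymptom_mean * 100:.1f}% vs {c.nonreport_mean * 100:.1f}% "
            f"(P={c.p_value:.3g})"
        )
    lines.append("")

    estimates = [e for e in result.estimates if e.mode == "report_days_only"]
    if estimates:
        lines.append("## Association of EMA responses with daily adherence")
        lines.append("")
        header = "| EMA item | " + " | ".join(LIKERT_LABELS) + " |"
        lines.append(header)
        lines.append("|" + "---|" * 5)
        by_item: dict[str, dict[int, ModelEstimate]] = {}
        for e in estimates:
            by_item.setdefault(e.item, {})[e.level] = e
        for item, cells in by_item.items():
            label = _ITEM_QUESTIONS.get(item, item)
            if item == "any_symptom":
                row = [
                    _estimate_cell(cells[lv]) if lv in cells else ""
                    for lv in (0, 1, 2, 3)
                ]
            else:
                row = [
                    _estimate_cell(cells[lv]) if lv in cells else "N/A"
                    for lv in (0, 1, 2, 3)
                ]
            lines.append("| " + " | ".join([label] + row) + " |")
        lines.append("")
    else:
        lines.append("## Association of EMA responses with daily adherence")
        lines.append("")
        lines.append("_No model estimates available._")
        lines.append("")
    if result.model_errors:
        lines.append("## Model diagnostics")
        lines.append("")
        for key, reason in sorted(result.model_errors.items()):
            lines.append(f"- {key}: {reason}")
        lines.append("")
    if result.sensitivity:
        flagged = [s for s in result.sensitivity if s.flagged]
        lines.append("## Imputation sensitivity")
        lines.append("")
        lines.append(
            f"- Comparisons: {len(result.sensitivity)}; flagged: {len(flagged)}"
        )
        for s in flagged:
            lines.append(
                f"- {s.item} level {s.level}: effect moves "
                f"{s.difference:+.1f} pp under imputation"
            )
        lines.append("")
    lines.append("## Provenance")
    lines.append("")
    lines.append(f"- Config hash: {result.provenance.get('config_hash')}")
    for key in (
        "n_participants",
        "n_events_in",
        "n_duplicates_removed",
        "n_reports",
        "n_daily_records",
    ):
        if key in result.provenance:
            lines.append(f"- {key}: {result.provenance[key]}")
    return "\n".join(lines) + "\n"
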