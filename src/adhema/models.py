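"""Linear mixed models linking daily EMA responses to daily adherence.

One model is fitted per EMA item (plus a binary any-symptom model):

    adherence_pct[i, d] = β0 + β_t · d + Σ_ℓ β_ℓ · 1[level[i, d] = ℓ]
                          + b_i + ε[i, d]

where ``adherence_pct`` is daily controller adherence on the 0–100 scale,
``d`` the study day (a linear time trend for the repeated-measures
structure), ``b_i`` a participant random intercept capturing each youth's
baseline adherence, and the fixed effects β_ℓ the percentage-point shift in
adherence on days at Likert level ℓ relative to the item's reference level.
Estimation is REML via :class:`statsmodels MixedLM` with Wald 95% intervals.

The primary frame keeps report days only; the imputation sensitivity frame
additionally includes non-report days with every item set to its reference
level, so imputed days inform the baseline but no item contrast.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .types import (
    EMA_ITEMS,
    REFERENCE_LEVELS,
    SYMPTOM_ITEMS,
    DailyRecord,
    ModelEstimate,
    ModelFitError,
    SensitivityComparison,
    StudyConfig,
)

MODES = ("report_days_only", "impute_nonreport")

_Z975 = float(stats.norm.ppf(0.975))


def _any_symptom(responses: dict[str, int], threshold: int) -> Optional[float]:
    present = [responses[i] for i in SYMPTOM_ITEMS if i in responses]
    if any(level >= threshold for level in present):
        return 1.0
    return 0.0 if present else np.nan


def build_model_frame(
    records: Iterable[DailyRecord],
    mode: str = "report_days_only",
    config: Optional[StudyConfig] = None,
) -> pd.DataFrame:
    """Assemble the participant-day model frame.

    ``report_days_only`` keeps days with an EMA report and defined
    adherence; ``impute_nonreport`` additionally includes non-report days
    with defined adherence, carrying every item at its reference level.
    Days with undefined adherence are excluded in both modes.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    config = (config or StudyConfig()).validate()
    rows = []
    for rec in records:
        if rec.daily_adherence is None:
            continue
        if rec.has_ema:
            row = {item: rec.responses.get(item, np.nan) for item in EMA_ITEMS}
            row["any_symptom"] = _any_symptom(
                rec.responses, config.symptom_threshold
            )
            row["imputed"] = False
        elif mode == "impute_nonreport":
            row = {item: float(REFERENCE_LEVELS[item]) for item in EMA_ITEMS}
            row["any_symptom"] = 0.0
            row["imputed"] = True
        else:
            continue
        row["participant_id"] = rec.participant_id
        row["study_day"] = rec.study_day
        row["adherence_pct"] = rec.daily_adherence * 100.0
        rows.append(row)
    columns = ["participant_id", "study_day", "adherence_pct", "imputed"]
    columns += list(EMA_ITEMS) + ["any_symptom"]
    frame = pd.DataFrame(rows, columns=columns)
    for column in (*EMA_ITEMS, "any_symptom", "adherence_pct"):
        frame[column] = frame[column].astype(float)
    frame.attrs["mode"] = mode
    return frame


def fit_adherence_model(
    frame: pd.DataFrame,
    item: str,
) -> list[ModelEstimate]:
    """Fit the daily-adherence mixed model for one EMA item.

    Returns one :class:`ModelEstimate` per Likert level (or per 0/1 level
    for ``any_symptom``): the reference row with effect 0 by construction,
    an estimated contrast for every observed non-reference level, and
    ``na_flag`` rows for levels absent from the data.
    """
    if item not in EMA_ITEMS and item != "any_symptom":
        raise ValueError(f"unknown item {item!r}")
    mode = frame.attrs.get("mode", "report_days_only")
    data = frame.dropna(subset=[item, "adherence_pct"]).copy()
    if data.empty:
        raise ModelFitError(item, "no usable participant-days")
    n_participants = data["participant_id"].nunique()
    if n_participants < 2:
        raise ModelFitError(
            item, "at least 2 participants required for a random intercept"
        )
    outcome = data["adherence_pct"].to_numpy(float)
    if np.allclose(outcome, outcome[0]):
        raise ModelFitError(item, "outcome has zero variance")

    reference = REFERENCE_LEVELS[item]
    all_levels = (0, 1) if item == "any_symptom" else (0, 1, 2, 3)
    observed = sorted(int(v) for v in data[item].unique())
    contrast_levels = [lv for lv in observed if lv != reference]

    exog = pd.DataFrame(
        {"Intercept": 1.0, "study_day": data["study_day"].to_numpy(float)},
        index=data.index,
    )
    for lv in contrast_levels:
        exog[f"level_{lv}"] = (data[item] == lv).astype(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            model = MixedLM(outcome, exog, groups=data["participant_id"])
            fit = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise ModelFitError(item, f"fit failed: {exc}") from exc
        params = np.asarray(fit.fe_params)
        bse = np.asarray(fit.bse_fe)
    if not np.all(np.isfinite(params)):
        raise ModelFitError(item, "non-finite fixed-effect estimates")

    re_var = float(np.asarray(fit.cov_re)[0, 0])
    resid_var = float(fit.scale)
    n_days = int(len(data))

    estimates: list[ModelEstimate] = []
    names = list(exog.columns)
    for lv in all_levels:
        if lv == reference:
            estimates.append(
                ModelEstimate(
                    item=item,
                    level=lv,
                    reference_level=reference,
                    effect=0.0,
                    n_days=n_days,
                    n_participants=n_participants,
                    re_var=re_var,
                    resid_var=resid_var,
                    is_reference=True,
                    mode=mode,
                )
            )
        elif lv in contrast_levels:
            k = names.index(f"level_{lv}")
            effect, se = float(params[k]), float(bse[k])
            z = effect / se if se > 0 else np.nan
            estimates.append(
                ModelEstimate(
                    item=item,
                    level=lv,
                    reference_level=reference,
                    effect=effect,
                    se=se,
                    ci_low=effect - _Z975 * se,
                    ci_high=effect + _Z975 * se,
                    p_value=float(2 * stats.norm.sf(abs(z)))
                    if np.isfinite(z)
                    else None,
                    n_days=n_days,
                    n_participants=n_participants,
                    re_var=re_var,
                    resid_var=resid_var,
                    mode=mode,
                )
            )
        else:
            estimates.append(
                ModelEstimate(
                    item=item,
                    level=lv,
                    reference_level=reference,
                    na_flag=True,
                    n_days=n_days,
                    n_participants=n_participants,
                    mode=mode,
                )
            )
    return estimates


def fit_all_items(
    frame: pd.DataFrame,
    items: Optional[Sequence[str]] = None,
) -> tuple[list[ModelEstimate], dict[str, str]]:
    """Fit every per-item model, collecting failures instead of raising."""
    items = list(items) if items is not None else ["any_symptom", *EMA_ITEMS]
    estimates: list[ModelEstimate] = []
    errors: dict[str, str] = {}
    for item in items:
        try:
            estimates.extend(fit_adherence_model(frame, item))
        except ModelFitError as exc:
            errors[item] = exc.reason
    return estimates, errors


def sensitivity_compare(
    report_est: ModelEstimate,
    imputed_est: ModelEstimate,
) -> SensitivityComparison:
    """Compare a report-days-only estimate with its imputed counterpart.

    Flags the comparison when imputation flips the sign of the effect or
    moves it by more than the report-only standard error — the signature of
    non-report days differing systematically from reported no-symptom days.
    """
    if (report_est.item, report_est.level) != (imputed_est.item, imputed_est.level):
        raise ValueError("estimates compare different items or levels")
    if report_est.effect is None or imputed_est.effect is None:
        return SensitivityComparison(
            item=report_est.item,
            level=report_est.level,
            report=report_est,
            imputed=imputed_est,
            difference=None,
            report_ci_width=_width(report_est),
            imputed_ci_width=_width(imputed_est),
            imputed_narrower=None,
        )
    difference = imputed_est.effect - report_est.effect
    rw, iw = _width(report_est), _width(imputed_est)
    sign_flip = (
        report_est.effect * imputed_est.effect < 0
        and not report_est.is_reference
    )
    shift = (
        report_est.se is not None
        and report_est.se > 0
        and abs(difference) > report_est.se
    )
    return SensitivityComparison(
        item=report_est.item,
        level=report_est.level,
        report=report_est,
        imputed=imputed_est,
        difference=difference,
        report_ci_width=rw,
        imputed_ci_width=iw,
        imputed_narrower=(iw < rw) if (rw is not None and iw is not None) else None,
        sign_flip=bool(sign_flip),
        shift_exceeds_se=bool(shift),
    )


def _width(est: ModelEstimate) -> Optional[float]:
    if est.ci_low is None or est.ci_high is None:
        return None
    return est.ci_high - est.ci_low
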