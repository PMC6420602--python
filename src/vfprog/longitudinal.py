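"""Early-detection analysis on time-truncated series.

Every metric is recomputed using only the visits on or before each cutoff
(half-year increments by default), imitating a clinic where the metrics are
refreshed at every visit while the reference label is the end-of-study
clinical determination.  AUC/pAUC at a cutoff come from logistic models
refit at that cutoff; sensitivity and specificity apply the FINAL-study
coefficients and thresholds to the cutoff predictors, since clinically the
operating rule is fixed once, at the end of model development.

``time_to_first_diagnosis`` walks each progressing eye's visits in order,
recomputing predictors on the accumulating history, and records the first
visit (in days from baseline, 365.25 days/year) at which the model's
probability crosses the threshold; eyes never flagged carry the last-visit
day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticModel, fit_logistic, pauc, roc
from .io import Cohort, VFSeries
from .pipeline import PredictorSettings, compute_predictors, required_tests

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DEFAULT_CUTOFFS = tuple(np.arange(0.5, 5.0, 0.5))

__all__ = [
    "truncate",
    "truncate_cohort",
    "evaluate_cutoffs",
    "time_to_first_diagnosis",
    "DetectionTimes",
    "DAYS_PER_YEAR",
    "DEFAULT_CUTOFFS",
]


def truncate(series: VFSeries, cutoff_years: float) -> VFSeries:
    """Keep tests at time <= cutoff; label unchanged.

    Idempotent and monotone: truncating at a then b equals truncating at
    min(a, b).  May return a single-test (unanalyzable) series.
    """
    if cutoff_years <= 0:
        raise ValueError("cutoff must be positive")
    kept = [t for t in series.tests if t.time_years <= cutoff_years]
    return VFSeries(eye_id=series.eye_id, tests=kept, label=series.label)


def truncate_cohort(cohort: Cohort, cutoff_years: float) -> Cohort:
    return Cohort([truncate(s, cutoff_years) for s in cohort])


def _binary_labels(labels: pd.Series) -> pd.Series:
    known = labels[labels != "unknown"]
    return (known == "progressing").astype(float)


def evaluate_cutoffs(
    cohort: Cohort,
    grid,
    models: dict[str, list[str]],
    cutoffs,
    settings: PredictorSettings | None = None,
    final_models: dict[str, DiagnosticModel] | None = None,
    final_thresholds: dict[str, float] | None = None,
    min_spec: float = 0.85,
) -> pd.DataFrame:
    """Per-cutoff AUC/pAUC (refit) and sens/spec (final rule) per model.

    ``final_models``/``final_thresholds`` are fitted on the full cohort when
    not supplied.  An eye enters a model's summary at a cutoff once it has
    accrued that model's minimum number of visits; cells where a class
    vanishes are reported as NaN.
    """
    settings = settings or PredictorSettings()
    labels = cohort.labels
    y_full = _binary_labels(labels)

    if final_models is None or final_thresholds is None:
        full_pred = compute_predictors(cohort, grid, settings)
        final_models, final_thresholds = {}, {}
        for name, cols in models.items():
            X = full_pred.loc[y_full.index, cols]
            m = fit_logistic(X, y_full)
            final_models[name] = m
            thr, _, _ = _threshold_of(m, X, y_full, min_spec)
            final_thresholds[name] = thr

    rows = []
    for cutoff in cutoffs:
        trunc = truncate_cohort(cohort, float(cutoff))
        pred = compute_predictors(trunc, grid, settings)
        for name, cols in models.items():
            X = pred.loc[y_full.index, cols]
            ok = X.notna().all(axis=1)
            n_eyes = int(ok.sum())
            yv = y_full[ok]
            row = {
                "cutoff_years": float(cutoff),
                "model": name,
                "n_eyes": n_eyes,
                "auc": np.nan,
                "pauc_norm": np.nan,
                "sens": np.nan,
                "spec": np.nan,
            }
            if n_eyes >= 2 and yv.nunique() == 2:
                refit = fit_logistic(X[ok], yv)
                row["auc"] = roc(refit.fitted_probs, yv).auc
                row["pauc_norm"] = pauc(refit.fitted_probs, yv, spec_lo=min_spec)
                probs_final = final_models[name].predict(X[ok])
                pred_pos = probs_final >= final_thresholds[name]
                n_pos = int((yv == 1).sum())
                n_neg = int((yv == 0).sum())
                if n_pos:
                    row["sens"] = float((pred_pos & (yv == 1)).sum() / n_pos)
                if n_neg:
                    row["spec"] = float((~pred_pos & (yv == 0)).sum() / n_neg)
            rows.append(row)
    return pd.DataFrame(rows)


def _threshold_of(model: DiagnosticModel, X: pd.DataFrame, y: pd.Series, min_spec: float):
    from .diagnostics import select_threshold

    ok = X.notna().all(axis=1)
    probs = model.predict(X[ok])
    return select_threshold(probs.to_numpy(), y[ok].to_numpy(), min_spec=min_spec)


@dataclass
class DetectionTimes:
    """Per-eye first-diagnosis days and the model mean."""

    table: pd.DataFrame  # eye_id, day, detected, last_visit_day
    mean_days: float


def time_to_first_diagnosis(
    cohort: Cohort,
    grid,
    model: DiagnosticModel,
    threshold: float,
    settings: PredictorSettings | None = None,
) -> DetectionTimes:
    """First visit at which the fixed model/threshold flags each progressing eye.

    Non-progressing eyes are skipped with a log line.  An eye with too few
    visits for the model at a visit is not evaluable there; undetected eyes
    are assigned their last-visit day.
    """
    settings = settings or PredictorSettings()
    min_tests = required_tests(model.predictor_names)
    skipped = sum(1 for s in cohort if s.label != "progressing")
    if skipped:
        logger.info("ignoring %d non-progressing eyes", skipped)

    rows = []
    for s in cohort:
        if s.label != "progressing":
            continue
        day = None
        for k in range(min_tests, s.n_tests + 1):
            prefix = VFSeries(eye_id=s.eye_id, tests=s.tests[:k], label=s.label)
            pred = compute_predictors(Cohort([prefix]), grid, settings)
            X = pred[model.predictor_names]
            if X.isna().any().any():
                continue
            prob = float(model.predict(X).iloc[0])
            if prob >= threshold:
                day = prefix.times[-1] * DAYS_PER_YEAR
                break
        detected = day is not None
        last_day = s.follow_up_years * DAYS_PER_YEAR
        rows.append(
            {
                "eye_id": s.eye_id,
                "day": float(day if detected else last_day),
                "detected": detected,
                "last_visit_day": float(last_day),
            }
        )
    table = pd.DataFrame(rows)
    return DetectionTimes(table=table, mean_days=float(table["day"].mean()) if len(table) else np.nan)
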