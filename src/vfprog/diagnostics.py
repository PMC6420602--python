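"""Diagnostic evaluation of progression predictors.

Each candidate metric's predictor set is combined into a logistic regression
against the clinical progression label; the fitted probability of
progression is the diagnostic score.  Models are compared by AIC, full AUC,
and partial AUC restricted to the clinically relevant specificity band
(85-100%), normalized by the band width so chance = 0.075 and a perfect
classifier = 1.  Added-value of a metric over another model is a
likelihood-ratio test of nested fits; AUC differences use the paired DeLong
test and pAUC differences a paired stratified bootstrap.  Operating
thresholds maximize sensitivity subject to specificity >= 85%.

All fits and ROC summaries are in-sample, mirroring a development-cohort
analysis; no train/test split is performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosticModel",
    "ROCSummary",
    "fit_logistic",
    "combine_with_gi",
    "lr_test",
    "roc",
    "pauc",
    "compare_auc",
    "metric_correlations",
    "select_threshold",
]


@dataclass
class DiagnosticModel:
    """A fitted logistic combiner of progression predictors."""

    predictor_names: list[str]
    params: np.ndarray  # intercept first
    llf: float
    aic: float
    fitted_probs: pd.Series  # indexed by eye id
    n_used: int
    n_dropped: int = 0

    @property
    def k(self) -> int:
        return len(self.params)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Predicted probability of progression for new predictor rows."""
        Z = np.column_stack([np.ones(len(X)), X[self.predictor_names].to_numpy(float)])
        eta = Z @ self.params
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X.index, name="prob")


@dataclass
class ROCSummary:
    """ROC points with full and partial (85-100% specificity) areas."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    pauc_norm: float
    chosen_threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    extras: dict = dc_field(default_factory=dict)


def _as_design(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.DataFrame(X).astype(float)
    y = pd.Series(np.asarray(y), index=X.index).astype(float)
    keep = X.notna().all(axis=1) & y.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with missing predictors", dropped)
    X, y = X.loc[keep], y.loc[keep]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot fit")
    return X, y.to_numpy()


def _check_rank(Z: np.ndarray, names: list[str]):
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, R = np.linalg.qr(Z)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Z.shape) * np.finfo(float).eps
        bad = [(["intercept"] + names)[j] for j in np.nonzero(diag < tol)[0]]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def fit_logistic(X: pd.DataFrame, y) -> DiagnosticModel:
    """Maximum-likelihood logistic regression of labels on predictors.

    Rows with missing predictors are dropped (count logged).  Coefficients
    above 20 in magnitude trigger a quasi-separation warning but the fit is
    retained.  AIC = 2k - 2 logL.
    """
    Xc, yv = _as_design(X, y)
    names = list(Xc.columns)
    Z = np.column_stack([np.ones(len(Xc)), Xc.to_numpy()])
    _check_rank(Z, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yv, Z).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        except np.linalg.LinAlgError:
            # singular Hessian under (quasi-)separation: fall back to a
            # gradient method; the coefficient-magnitude check below warns
            res = sm.Logit(yv, Z).fit(method="lbfgs", maxiter=500, disp=0)
    params = np.asarray(res.params)
    if np.abs(params).max() > 20:
        warnings.warn(
            "very large coefficients: possible quasi-separation", UserWarning
        )
    probs = pd.Series(res.predict(Z), index=Xc.index, name="prob")
    return DiagnosticModel(
        predictor_names=names,
        params=params,
        llf=float(res.llf),
        aic=float(2 * len(params) - 2 * res.llf),
        fitted_probs=probs,
        n_used=len(Xc),
        n_dropped=len(X) - len(Xc),
    )


def lr_test(full: DiagnosticModel, reduced: DiagnosticModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested logistic models: (stat, df, p)."""
    df = full.k - reduced.k
    if df <= 0:
        raise ValueError("'full' must have more parameters than 'reduced'")
    stat = 2.0 * (full.llf - reduced.llf)
    return stat, df, float(stats.chi2.sf(max(stat, 0.0), df))


def combine_with_gi(
    gi_predictors: pd.DataFrame, other_predictors: pd.DataFrame, y
) -> tuple[DiagnosticModel, float]:
    """Fit GI predictors plus another metric's predictors jointly.

    Returns the combined model and the likelihood-ratio p-value for the
    added metric over the GI-only model (both fitted on the rows where all
    columns are available).
    """
    X = pd.concat([gi_predictors, other_predictors], axis=1)
    if X.columns.duplicated().any():
        raise ValueError(
            f"duplicated predictor columns: {list(X.columns[X.columns.duplicated()])}"
        )
    keep = X.notna().all(axis=1)
    combined = fit_logistic(X.loc[keep], pd.Series(np.asarray(y), index=X.index).loc[keep])
    gi_only = fit_logistic(gi_predictors.loc[keep], pd.Series(np.asarray(y), index=X.index).loc[keep])
    _, _, p = lr_test(combined, gi_only)
    return combined, p


def _check_classes(labels) -> np.ndarray:
    yv = np.asarray(labels, dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("labels contain a single class")
    return yv


def roc(probs, labels, spec_lo: float = 0.85, min_spec: float | None = None) -> ROCSummary:
    """ROC points, AUC (Mann-Whitney, ties at 0.5), and normalized pAUC."""
    yv = _check_classes(labels)
    pv = np.asarray(probs, dtype=float)
    fpr, tpr, thr = roc_curve(yv, pv, drop_intermediate=False)
    auc = float(roc_auc_score(yv, pv))
    p = pauc(pv, yv, spec_lo=spec_lo)
    summary = ROCSummary(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, pauc_norm=p)
    if min_spec is not None:
        t, s, sp = select_threshold(pv, yv, min_spec=min_spec)
        summary.chosen_threshold, summary.sensitivity, summary.specificity = t, s, sp
    return summary


def pauc(probs, labels, spec_lo: float = 0.85) -> float:
    """Partial AUC over specificity in [spec_lo, 1], normalized by the band.

    The raw area under the (tie-handled, trapezoidal) ROC for
    FPR in [0, 1 - spec_lo], with linear interpolation at the band edge,
    divided by (1 - spec_lo).  Chance = (1 - spec_lo) / 2.
    """
    if not 0 < spec_lo < 1:
        raise ValueError(f"spec_lo must be in (0, 1), got {spec_lo}")
    yv = _check_classes(labels)
    pv = np.asarray(probs, dtype=float)
    fpr, tpr, _ = roc_curve(yv, pv, drop_intermediate=False)
    fmax = 1.0 - spec_lo
    tpr_edge = np.interp(fmax, fpr, tpr)
    keep = fpr < fmax
    fx = np.concatenate([fpr[keep], [fmax]])
    fy = np.concatenate([tpr[keep], [tpr_edge]])
    raw = float(np.trapezoid(fy, fx))
    return raw / fmax


# --- DeLong paired AUC comparison ------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(probs: np.ndarray, y: np.ndarray):
    pos = probs[y == 1]
    neg = probs[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    return auc, v10, v01


def _delong_test(pa: np.ndarray, pb: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    auc_a, v10_a, v01_a = _delong_components(pa, y)
    auc_b, v10_b, v01_b = _delong_components(pb, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        return diff, 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return diff, float(2.0 * stats.norm.sf(abs(z)))


def compare_auc(
    probs_a,
    probs_b,
    labels,
    kind: str = "auc",
    n_boot: int = 2000,
    seed: int = 0,
    spec_lo: float = 0.85,
) -> float:
    """Two-sided p-value for a paired difference in AUC or pAUC.

    AUC: DeLong's paired test.  pAUC: stratified paired bootstrap over eyes
    (classes resampled separately so both are always present); the p-value
    is twice the smaller tail proportion of the bootstrap difference.
    """
    pa = np.asarray(probs_a, dtype=float)
    pb = np.asarray(probs_b, dtype=float)
    yv = _check_classes(labels)
    if not len(pa) == len(pb) == len(yv):
        raise ValueError("probs_a, probs_b and labels must have equal length")
    if kind == "auc":
        _, p = _delong_test(pa, pb, yv)
        return p
    if kind != "pauc":
        raise ValueError("kind must be 'auc' or 'pauc'")
    rng = np.random.default_rng(seed)
    idx_pos = np.nonzero(yv == 1)[0]
    idx_neg = np.nonzero(yv == 0)[0]
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx_pos, len(idx_pos)), rng.choice(idx_neg, len(idx_neg))]
        )
        yb = yv[take]
        diffs[b] = pauc(pa[take], yb, spec_lo) - pauc(pb[take], yb, spec_lo)
    lo = float(np.mean(diffs <= 0))
    hi = float(np.mean(diffs >= 0))
    return min(1.0, 2.0 * min(lo, hi))


def metric_correlations(prob_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and two-sided p) between each pair of metric scores."""
    df = pd.DataFrame(prob_matrix).astype(float)
    if len(df) < 3:
        raise ValueError("need at least 3 eyes for correlations")
    if df.isna().any().any():
        raise ValueError("prob_matrix contains missing entries")
    zero_var = [c for c in df.columns if df[c].std(ddof=0) == 0]
    if zero_var:
        raise ValueError(f"zero-variance columns: {zero_var}")
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            rr, pp = stats.pearsonr(df[a], df[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


def select_threshold(probs, labels, min_spec: float = 0.85) -> tuple[float, float, float]:
    """Operating threshold: maximize sensitivity s.t. specificity >= min_spec.

    Candidates are midpoints between adjacent distinct scores plus +/-inf;
    classification is score >= threshold.  Ties prefer higher specificity,
    then the lower threshold.  The +inf candidate (sensitivity 0,
    specificity 1) guarantees a feasible answer.
    """
    yv = _check_classes(labels)
    pv = np.asarray(probs, dtype=float)
    uniq = np.unique(pv)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    n_pos = (yv == 1).sum()
    n_neg = (yv == 0).sum()
    best = None
    for c in cands:
        pred = pv >= c
        sens = float((pred & (yv == 1)).sum() / n_pos)
        spec = float((~pred & (yv == 0)).sum() / n_neg)
        if spec < min_spec:
            continue
        key = (sens, spec, -c if np.isfinite(c) else -np.inf if c == np.inf else np.inf)
        if best is None or key > best[0]:
            best = (key, (float(c), sens, spec))
    return best[1]
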