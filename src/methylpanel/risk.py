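"""Risk-model evaluation: logistic ORs, Cox HRs, discrimination, RTL slopes.

Biomarkers are evaluated at each subject's baseline (earliest) sample:
logistic regression gives odds ratios per SD of the z-scored biomarker,
Cox proportional-hazards regression gives hazard ratios with time measured
in years from the baseline sample to AD onset (cases) or last follow-up
(controls, censored), and the C-statistic — the probability that a random
case outscores a random control, identical to the ROC AUC — compares
discriminatory accuracy across models.  All models adjust for APOE e4
carriage, granulocyte proportion, sex, and chronological age, with
continuous predictors z-scored within the cohort being analyzed so effect
sizes read as "per one SD increase".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from sklearn import metrics

logger = logging.getLogger(__name__)


@dataclass
class RiskModelResult:
    """Tidy per-term estimates plus model-level discrimination."""

    model: str
    terms: pd.DataFrame        # term, estimate, ratio, ci_low, ci_high, p
    auc: float | None = None
    n_cases: int = 0
    n_controls: int = 0
    flags: dict = field(default_factory=dict)

    def ratio(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "ratio"])


def zscale(values) -> pd.Series:
    """Scale to zero mean and unit sample SD (ddof=1)."""
    x = pd.Series(values).astype(float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero variance; cannot z-score")
    return (x - x.mean()) / sd


def baseline_subsample(sheet: pd.DataFrame) -> pd.DataFrame:
    """Earliest available sample per subject (the baseline time-point)."""
    return (sheet.sort_values(["subject_id", "time"])
            .groupby("subject_id", as_index=False).first())


def _assemble(outcome, predictors: pd.DataFrame, z_continuous: bool):
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = predictors.astype(float).copy()
    if z_continuous:
        for col in X.columns:
            vals = X[col]
            if vals.nunique() > 2:  # leave binary indicators on their own scale
                X[col] = zscale(vals).to_numpy()
    return y, X


def fit_logistic(outcome, predictors: pd.DataFrame,
                 z_continuous: bool = True,
                 name: str = "logistic") -> RiskModelResult:
    """Maximum-likelihood logistic regression with Wald CIs and the AUC.

    Continuous predictors (more than two distinct values) are z-scored when
    ``z_continuous``, so odds ratios are per one SD increase.  Perfect
    separation is detected and flagged rather than silently diverging.
    """
    y, X = _assemble(outcome, predictors, z_continuous)
    Xc = sm.add_constant(X, has_constant="add")
    flags = {}
    try:
        import warnings as _warnings
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        fitted = fit.predict(Xc)
        if np.abs(params).max() > 15 or not np.isfinite(bse).all():
            flags["separation"] = True
    except Exception as exc:
        # clean separation makes the Hessian singular: report a weakly
        # ridge-penalized fit, flagged, instead of silently diverging
        flags["separation"] = True
        logger.warning("logistic fit flagged: %s", exc)
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=100.0, max_iter=1000)
        lr.fit(Xc.drop(columns="const"), y)
        coef = np.concatenate([[lr.intercept_[0]], lr.coef_[0]])
        params = pd.Series(coef, index=Xc.columns)
        bse = pd.Series(np.nan, index=Xc.columns)
        pvals = pd.Series(np.nan, index=Xc.columns)
        fitted = lr.predict_proba(Xc.drop(columns="const"))[:, 1]
    zcrit = 1.959963984540054
    terms = pd.DataFrame({
        "term": params.index,
        "estimate": params.values,
        "ratio": np.exp(params.values),
        "ci_low": np.exp(params.values - zcrit * bse.values),
        "ci_high": np.exp(params.values + zcrit * bse.values),
        "p": pvals.values,
    })
    auc = c_statistic(fitted, y)
    return RiskModelResult(model=name, terms=terms, auc=auc,
                           n_cases=int(y.sum()), n_controls=int((1 - y).sum()),
                           flags=flags)


def fit_cox(time_to_event, event, predictors: pd.DataFrame,
            z_continuous: bool = True, name: str = "cox") -> RiskModelResult:
    """Cox proportional-hazards fit (Efron tie handling via lifelines)."""
    t = np.asarray(time_to_event, dtype=float)
    e = np.asarray(event, dtype=float)
    if (t < 0).any():
        raise ValueError("event/censoring times must be nonnegative")
    if e.sum() == 0:
        raise ValueError("no events observed")
    X = predictors.astype(float).copy()
    if z_continuous:
        for col in X.columns:
            if X[col].nunique() > 2:
                X[col] = zscale(X[col]).to_numpy()
    flags = {}
    # collinearity check on the predictor block (before fitting)
    varying = X.loc[:, X.nunique() > 1]
    if varying.shape[1] > 1:
        corr = varying.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if (corr.values > 0.95).any():
            hi = corr.stack().idxmax()
            flags["collinearity"] = f"{hi[0]}~{hi[1]}"
            logger.warning("near-collinear Cox predictors: %s",
                           flags["collinearity"])
    df = X.copy()
    df["_time"] = np.maximum(t, 1e-9)
    df["_event"] = e
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event",
                fit_options={"precision": 1e-12})
    except Exception as exc:
        # singular information matrix (e.g. duplicated predictors): retry
        # with a small ridge penalty so the flagged result is still reported
        flags["penalized_refit"] = str(exc).splitlines()[0]
        cph = CoxPHFitter(penalizer=1e-3)
        cph.fit(df, duration_col="_time", event_col="_event")
    summ = cph.summary
    if np.abs(summ["coef"]).max() > 15:
        flags["monotone_likelihood"] = True
    terms = pd.DataFrame({
        "term": summ.index,
        "estimate": summ["coef"].values,
        "ratio": summ["exp(coef)"].values,
        "ci_low": np.exp(summ["coef lower 95%"].values),
        "ci_high": np.exp(summ["coef upper 95%"].values),
        "p": summ["p"].values,
    })
    return RiskModelResult(model=name, terms=terms, auc=None,
                           n_cases=int(e.sum()), n_controls=int((1 - e).sum()),
                           flags=flags)


def c_statistic(scores, labels) -> float:
    """P(random case outscores random control), ties credited 0.5 (= ROC AUC)."""
    labels = np.asarray(labels, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return float(metrics.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points (fpr, tpr, threshold)."""
    fpr, tpr, thr = metrics.roc_curve(np.asarray(labels, dtype=float),
                                      np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def rtl_slope(sheet: pd.DataFrame, value_col: str = "rtl",
              age_col: str = "age") -> pd.Series:
    """Per-subject OLS slope of relative telomere length on age (per year).

    Subjects with fewer than two visits get a missing slope with a warning.
    """
    slopes = {}
    n_short = 0
    for sid, grp in sheet.groupby("subject_id"):
        if len(grp) < 2 or grp[age_col].nunique() < 2:
            slopes[sid] = np.nan
            n_short += 1
            continue
        slopes[sid] = float(np.polyfit(grp[age_col], grp[value_col], 1)[0])
    if n_short:
        logger.warning("%d subjects lack >=2 visits; slope set missing", n_short)
    return pd.Series(slopes, name="rtl_slope")


COVARIATES = ["apoe_e4", "sex_male", "granulocyte", "age"]


def _covariate_frame(sheet: pd.DataFrame, granulocyte: pd.Series) -> pd.DataFrame:
    g = granulocyte.reindex(sheet["sample_id"])
    if g.isna().any():
        raise ValueError("granulocyte proportion missing for some samples")
    return pd.DataFrame({
        "apoe_e4": sheet["apoe_e4"].to_numpy(dtype=float),
        "sex_male": (sheet["sex"].to_numpy() == "M").astype(float),
        "granulocyte": g.to_numpy(dtype=float),
        "age": sheet["age"].to_numpy(dtype=float),
    }, index=sheet["sample_id"])


def validate_external(panel, external_matrix, external_sheet: pd.DataFrame,
                      granulocyte: pd.Series,
                      scan_results: pd.DataFrame | None = None) -> dict:
    """External validation of a panel on a cross-sectional cohort.

    Fits covariate-only and covariate+score logistic models (per-SD OR and
    AUC for each) and, when discovery ``scan_results`` are given, runs the
    per-CpG univariate logistic replication with direction-concordance
    counting: a panel CpG replicates in direction when the sign of its
    adjusted log-OR matches the sign of its discovery AD estimate.
    """
    from .ewas import panel_score

    score = panel_score(external_matrix, panel)
    sheet = external_sheet.set_index("sample_id").loc[score.index]
    sheet.index.name = "sample_id"
    sheet = sheet.reset_index()
    cov = _covariate_frame(sheet, granulocyte)
    y = sheet["ad"].to_numpy(dtype=float)

    base = fit_logistic(y, cov, name="covariates_only")
    with_score = fit_logistic(
        y, cov.assign(panel_score=score.to_numpy()), name="covariates_plus_panel")

    out = {
        "covariates_only": base,
        "covariates_plus_panel": with_score,
        "panel_or_per_sd": with_score.ratio("panel_score"),
        "auc_covariates": base.auc,
        "auc_with_panel": with_score.auc,
    }
    if scan_results is not None:
        rows = []
        concordant = 0
        for probe in panel.probes:
            beta = external_matrix.values.loc[probe]
            res = fit_logistic(y, cov.assign(cpg=beta.to_numpy()),
                               name=f"cpg:{probe}")
            t = res.terms.set_index("term")
            est = float(t.loc["cpg", "estimate"])
            pv = float(t.loc["cpg", "p"])
            disc = float(scan_results.loc[probe, "estimate"])
            same = bool(np.sign(est) == np.sign(disc))
            concordant += same
            rows.append({"probe": probe, "log_or": est, "or": np.exp(est),
                         "p": pv, "discovery_estimate": disc,
                         "direction_concordant": same,
                         "nominally_significant": pv < 0.05})
        out["per_cpg"] = pd.DataFrame(rows)
        out["n_direction_concordant"] = int(concordant)
    return out
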