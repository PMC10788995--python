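"""Validation of a risk score against right-censored survival.

The central estimator is the cumulative-case / dynamic-control time-dependent
ROC at a fixed horizon tau (default 365 days): cases experienced the event by
tau, controls are event-free beyond tau, and samples censored before tau are
handled by inverse-probability-of-censoring weights from the Kaplan-Meier
estimate of the censoring distribution.  Without censoring the estimator
reduces exactly to the ordinary binary ROC of the event-by-tau indicator.

The optimal cutoff maximizes Youden's J = sens + spec - 1 (ties broken toward
the larger threshold, assigning fewer samples to high risk); the resulting
high/low stratification feeds Kaplan-Meier curves, the two-group log-rank
test, and univariate/multivariate Cox models with ordinal-encoded clinical
covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ClinicalTable, ValidationError
from .signature import CoxFit

logger = logging.getLogger("lncpairsig")

__all__ = [
    "ROCCurve",
    "RiskStratification",
    "KMEstimate",
    "survival_roc",
    "optimal_cutoff",
    "stratify",
    "kaplan_meier",
    "logrank_test",
    "multivariate_cox",
    "compare_roc_features",
    "encode_clinical",
]

GRADE_CODES = {"G1": 1, "G2": 2, "G3": 3, "G4": 4}
STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}
SEX_CODES = {"male": 1, "female": 0}


@dataclass
class ROCCurve:
    horizon: float
    thresholds: np.ndarray  # descending; starts at +inf
    sens: np.ndarray
    spec: np.ndarray
    auc: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "sens": self.sens, "spec": self.spec}
        )


@dataclass
class RiskStratification:
    scores: pd.Series
    cutoff: float
    labels: pd.Series  # {"high", "low"}

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "label": self.labels})


@dataclass
class KMEstimate:
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # product-limit value at each event time
    at_risk: np.ndarray
    events: np.ndarray


def _censoring_survival(time: np.ndarray, event: np.ndarray):
    """KM estimate of the censoring distribution G(t) = P(C > t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    return kmf


def survival_roc(scores: pd.Series, surv: ClinicalTable, horizon: float = 365.0) -> ROCCurve:
    """IPCW cumulative/dynamic ROC and trapezoidal AUC at ``horizon`` days."""
    if list(scores.index) != surv.sample_ids:
        scores = scores.reindex(surv.sample_ids)
        if scores.isna().any():
            raise ValidationError("scores missing for some survival samples")
    time = surv.os_time.to_numpy()
    event = surv.os_event.to_numpy()
    s = scores.to_numpy(dtype=float)
    if horizon <= 0 or horizon > time.max():
        raise ValidationError(
            f"horizon {horizon} outside observed follow-up (max {time.max():.1f})"
        )
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if case.sum() == 0:
        raise ValidationError(f"no events by horizon {horizon}")
    if control.sum() == 0:
        raise ValidationError(f"no samples event-free beyond horizon {horizon}")

    g = _censoring_survival(time, event)
    # case weight 1/G(T_i-): left limit just before the event time
    g_case = g.predict(time[case] * (1 - 1e-12)).to_numpy(dtype=float)
    if (g_case <= 0).any():
        raise ValidationError("censoring survival reaches 0 before an observed event")
    w_case = 1.0 / g_case
    # control weights 1/G(tau) are constant and cancel in the proportions

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    w_total = w_case.sum()
    n_control = control.sum()
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    s_case = s[case]
    s_control = s[control]
    for i, c in enumerate(thresholds):
        sens[i] = w_case[s_case > c].sum() / w_total
        spec[i] = (s_control <= c).sum() / n_control
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(horizon=float(horizon), thresholds=thresholds, sens=sens, spec=spec, auc=auc)


def optimal_cutoff(roc: ROCCurve) -> float:
    """Threshold maximizing Youden's J; ties go to the larger threshold."""
    j = roc.sens + roc.spec - 1.0
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise ValidationError("degenerate ROC curve with no finite thresholds")
    j_f = j[finite]
    t_f = roc.thresholds[finite]
    best_j = j_f.max()
    if best_j <= 0:
        logger.warning("optimal_cutoff: no threshold attains J > 0 (uninformative scores)")
    # thresholds are descending, so the first argmax is the largest threshold
    return float(t_f[int(np.argmax(j_f))])


def stratify(scores: pd.Series, cutoff: float) -> RiskStratification:
    """Label samples high (score > cutoff, strict) or low risk."""
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be > 0, got {cutoff}")
    labels = pd.Series(
        np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low"),
        index=scores.index,
        dtype=object,
        name="label",
    )
    n_high = int((labels == "high").sum())
    n_low = len(labels) - n_high
    if n_high == 0 or n_low == 0:
        raise ValidationError(
            f"stratification at cutoff {cutoff} leaves an empty group "
            f"(high={n_high}, low={n_low})"
        )
    logger.info("stratify: %d high-risk / %d low-risk at cutoff %.4g", n_high, n_low, cutoff)
    return RiskStratification(scores=scores, cutoff=float(cutoff), labels=labels)


def kaplan_meier(surv: ClinicalTable) -> KMEstimate:
    """Product-limit estimate; censored times shrink the risk set steplessly."""
    if len(surv.sample_ids) == 0:
        raise ValidationError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.os_time, event_observed=surv.os_event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv_vals = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMEstimate(
        times=times,
        survival=surv_vals,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
    )


def logrank_test(strat: RiskStratification, surv: ClinicalTable) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    labels = strat.labels.reindex(surv.sample_ids)
    if labels.isna().any():
        raise ValidationError("stratification missing for some survival samples")
    high = labels == "high"
    if high.all() or (~high).all():
        raise ValidationError("log-rank test requires two non-empty groups")
    time = surv.os_time.to_numpy()
    event = surv.os_event.to_numpy()
    res = _ll_logrank(time[high.to_numpy()], time[~high.to_numpy()],
                      event_observed_A=event[high.to_numpy()],
                      event_observed_B=event[~high.to_numpy()])
    return float(res.test_statistic), float(res.p_value)


def encode_clinical(clin: ClinicalTable) -> pd.DataFrame:
    """Ordinal-encode covariates: grade/stage 1-4, male=1/female=0, age as-is."""
    df = clin.data
    out = pd.DataFrame(index=df.index)
    out["age"] = pd.to_numeric(df["age"], errors="coerce")
    out["sex"] = df["sex"].map(SEX_CODES)
    out["grade"] = df["grade"].map(GRADE_CODES)
    out["stage"] = df["stage"].map(STAGE_CODES)
    return out


def _check_collinearity(xmat: pd.DataFrame) -> None:
    arr = xmat.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < arr.shape[1]:
        # identify a minimal offending set by greedy inclusion
        offending: list[str] = []
        kept_idx: list[int] = []
        for i, col in enumerate(xmat.columns):
            trial = centered[:, kept_idx + [i]]
            if np.linalg.matrix_rank(trial) == len(kept_idx) + 1:
                kept_idx.append(i)
            else:
                offending.append(col)
        raise ValidationError(f"perfectly collinear covariates: {offending}")


def multivariate_cox(surv: ClinicalTable, terms: pd.DataFrame) -> list[CoxFit]:
    """Joint Cox PH fit of the given numeric terms (Efron ties, Wald inference).

    Rows with missing values are dropped listwise (and logged).  Perfect
    collinearity raises, naming the offending terms.
    """
    terms = terms.reindex(surv.sample_ids)
    df = terms.copy()
    df["time"] = surv.os_time
    df["event"] = surv.os_event
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info("multivariate_cox: dropped %d samples with missing values", n_before - len(df))
    if df.empty:
        raise ValidationError("no complete cases for multivariate Cox")
    _check_collinearity(df[terms.columns])
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise ValidationError(f"multivariate Cox did not converge: {err}") from err
    n_events = int(df["event"].sum())
    fits = []
    for term in terms.columns:
        row = cph.summary.loc[term]
        fits.append(
            CoxFit(
                term=str(term),
                beta=float(row["coef"]),
                hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]),
                n=len(df),
                n_events=n_events,
                significant=bool(row["p"] < 0.05),
            )
        )
    return fits


def compare_roc_features(
    surv: ClinicalTable, features: pd.DataFrame, horizon: float = 365.0
) -> pd.DataFrame:
    """Time-dependent AUC per feature at a shared horizon, sorted descending."""
    rows = []
    for col in features.columns:
        vals = pd.to_numeric(features[col], errors="coerce")
        mask = vals.notna()
        sub = ClinicalTable(surv.data.loc[mask[mask].index])
        roc = survival_roc(vals[mask], sub, horizon)
        rows.append({"feature": col, "auc": roc.auc, "n": int(mask.sum())})
    out = pd.DataFrame(rows).set_index("feature").sort_values("auc", ascending=False)
    return out
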