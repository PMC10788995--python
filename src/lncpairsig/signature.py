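"""Prognostic signature selection over pair features and the risk score.

The modelling chain follows the usual two-stage recipe for high-dimensional
survival features:

1. each valid pair indicator is screened by a univariate Cox proportional-
   hazards fit (Efron tie handling, Wald inference); pairs with P below the
   gate (default 0.05) proceed;
2. the surviving indicators enter an L1-penalized Cox model; the penalty is
   chosen at the minimum of the cross-validated partial-likelihood deviance
   (folds stratified by event status, reproducible from a seed), and the
   nonzero-coefficient pairs form the signature.

The per-sample risk score is ``exp(sum_i beta_i * x_i)`` — strictly positive,
equal to 1 when every indicator is 0, and inheriting the pair features'
invariance to per-sample monotone transforms of expression.

The published 5-pair HCC signature ships as a constant
(:func:`published_signature`) so the scoring/stratification stages can be run
without refitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io import ClinicalTable, ValidationError
from .pairs import PairMatrix, pair_id

logger = logging.getLogger("lncpairsig")

__all__ = [
    "CoxFit",
    "SignatureModel",
    "EmptySignatureError",
    "univariate_cox_screen",
    "fit_lasso_cox",
    "compute_risk_score",
    "published_signature",
]


class EmptySignatureError(RuntimeError):
    """The penalty shrank every coefficient to zero."""


@dataclass
class CoxFit:
    """One term of a Cox proportional-hazards fit (Wald inference)."""

    term: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    converged: bool = True
    significant: bool = False


@dataclass
class SignatureModel:
    """Ordered lncRNA pairs with Cox coefficients defining exp(sum beta*x)."""

    pairs: list[tuple[str, str]]
    coefficients: list[float]
    lambda_: float | None
    provenance: str  # {"fitted", "published"}

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.coefficients):
            raise ValidationError("one coefficient per pair required")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("signature pairs must be unique")
        if any(c == 0 for c in self.coefficients):
            raise ValidationError("signature coefficients must be nonzero")

    @property
    def pair_ids(self) -> list[str]:
        return [pair_id(a, b) for a, b in self.pairs]

    def to_yaml(self, path) -> None:
        doc = {
            "provenance": self.provenance,
            "lambda": None if self.lambda_ is None else float(self.lambda_),
            "pairs": [
                {"lnc_a": a, "lnc_b": b, "coefficient": float(c)}
                for (a, b), c in zip(self.pairs, self.coefficients)
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SignatureModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            pairs=[(p["lnc_a"], p["lnc_b"]) for p in doc["pairs"]],
            coefficients=[float(p["coefficient"]) for p in doc["pairs"]],
            lambda_=doc.get("lambda"),
            provenance=doc.get("provenance", "fitted"),
        )


def _check_alignment(pm: PairMatrix, surv: ClinicalTable) -> None:
    if pm.sample_ids != surv.sample_ids:
        raise ValidationError("pair matrix and survival data must share sample order")


def univariate_cox_screen(
    pm: PairMatrix, surv: ClinicalTable, p_max: float = 0.05
) -> list[CoxFit]:
    """Single-covariate Cox PH fit per pair; fits with p < p_max are flagged.

    Non-converging fits are returned with ``converged=False`` and never
    flagged significant.
    """
    _check_alignment(pm, surv)
    time = surv.os_time.to_numpy()
    event = surv.os_event.to_numpy()
    n_events = int(event.sum())
    if n_events == 0:
        raise ValidationError("univariate Cox screen requires at least one event")
    fits: list[CoxFit] = []
    for pid in pm.pair_ids:
        x = pm.indicators.loc[pid].to_numpy(dtype=float)
        df = pd.DataFrame({"x": x, "time": time, "event": event})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            row = cph.summary.loc["x"]
            fit = CoxFit(
                term=pid,
                beta=float(row["coef"]),
                hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]),
                n=len(x),
                n_events=n_events,
                converged=True,
            )
            fit.significant = fit.p < p_max
        except ConvergenceError:
            logger.warning("univariate Cox fit for pair %s did not converge; excluded", pid)
            fit = CoxFit(pid, np.nan, np.nan, np.nan, np.nan, np.nan, len(x), n_events, False)
        fits.append(fit)
    logger.info(
        "univariate_cox_screen: %d/%d pairs significant at p < %g",
        sum(f.significant for f in fits),
        len(fits),
        p_max,
    )
    return fits


def cox_fits_frame(fits: list[CoxFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [f.term for f in fits],
            "beta": [f.beta for f in fits],
            "hr": [f.hr for f in fits],
            "ci_low": [f.ci_low for f in fits],
            "ci_high": [f.ci_high for f in fits],
            "p": [f.p for f in fits],
            "n": [f.n for f in fits],
            "n_events": [f.n_events for f in fits],
            "significant": [f.significant for f in fits],
        }
    ).set_index("term")


def breslow_partial_loglik(
    beta: np.ndarray, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow log partial likelihood, used to score held-out folds."""
    eta = x @ beta
    order = np.argsort(-time, kind="stable")  # descending: risk sets are prefixes
    eta_o = eta[order]
    time_o = time[order]
    event_o = event[order]
    log_risk = np.logaddexp.accumulate(eta_o)
    # at tied times the risk set includes all samples with t_j >= t_i
    ll = 0.0
    i = 0
    n = len(time_o)
    while i < n:
        j = i
        while j + 1 < n and time_o[j + 1] == time_o[i]:
            j += 1
        denom = log_risk[j]
        for k in range(i, j + 1):
            if event_o[k]:
                ll += eta_o[k] - denom
        i = j + 1
    return float(ll)


def fit_lasso_cox(
    pm: PairMatrix,
    surv: ClinicalTable,
    n_folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
) -> SignatureModel:
    """L1-penalized Cox over pair indicators; lambda by CV deviance minimum.

    ``alpha`` forces a specific penalty (skipping cross-validation), which is
    mainly useful for testing the shrinkage limits.  Indicators enter
    unstandardized, so coefficients stay on the 0/1 scale of the published
    model.
    """
    _check_alignment(pm, surv)
    x = pm.indicators.to_numpy(dtype=float).T  # samples x pairs
    time = surv.os_time.to_numpy()
    event = surv.os_event.to_numpy().astype(bool)
    if x.shape[1] < 1:
        raise ValidationError("LASSO-Cox requires at least one candidate pair")
    if alpha is None and x.shape[1] < 2:
        raise ValidationError("cross-validated LASSO-Cox requires >= 2 candidate pairs")
    n_events = int(event.sum())
    if alpha is None and n_events < n_folds:
        raise ValidationError(f"need >= {n_folds} events for {n_folds}-fold CV, got {n_events}")
    y = Surv.from_arrays(event=event, time=time)

    def _fit(alphas=None):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            alphas=alphas,
            n_alphas=n_alphas,
            alpha_min_ratio=alpha_min_ratio,
            normalize=False,
            max_iter=100000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, y)
        return model

    if alpha is not None:
        model = _fit(alphas=[max(alpha, 1e-9)])
        coefs = model.coef_[:, 0]
        chosen = float(alpha)
    else:
        path_model = _fit()
        alphas = np.asarray(path_model.alphas_)
        folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        deviance = np.zeros((n_folds, len(alphas)))
        for k, (tr, te) in enumerate(folds.split(x, event.astype(int))):
            fold_model = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=list(alphas), normalize=False, max_iter=100000
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold_model.fit(x[tr], y[tr])
            fitted = np.asarray(fold_model.alphas_)
            for a_idx, a in enumerate(alphas):
                j = int(np.argmin(np.abs(fitted - a)))
                beta = fold_model.coef_[:, j]
                deviance[k, a_idx] = -2.0 * breslow_partial_loglik(
                    beta, x[te], time[te], event[te].astype(int)
                )
        mean_dev = deviance.mean(axis=0)
        best = int(np.argmin(mean_dev))
        chosen = float(alphas[best])
        logger.info("fit_lasso_cox: lambda_min=%.5g (CV deviance %.4f)", chosen, mean_dev[best])
        model = _fit(alphas=list(alphas))
        coefs = model.coef_[:, best]

    nz = np.flatnonzero(coefs)
    if nz.size == 0:
        raise EmptySignatureError(
            f"all coefficients are zero at lambda={chosen:.5g}; use a weaker penalty"
        )
    pairs = [pm.pairs[i] for i in nz]
    return SignatureModel(
        pairs=pairs,
        coefficients=[float(coefs[i]) for i in nz],
        lambda_=chosen,
        provenance="fitted",
    )


def compute_risk_score(model: SignatureModel, pm: PairMatrix) -> pd.Series:
    """Per-sample risk score exp(sum_i beta_i * x_i); strictly positive."""
    missing = [p for p in model.pair_ids if p not in pm.indicators.index]
    if missing:
        raise ValidationError(f"pair matrix is missing signature pairs: {missing}")
    x = pm.indicators.loc[model.pair_ids].to_numpy(dtype=float)
    beta = np.asarray(model.coefficients)
    score = np.exp(beta @ x)
    return pd.Series(score, index=pm.sample_ids, name="risk_score")


def published_signature() -> SignatureModel:
    """The published 5-pair HCC vascular-invasion signature (fixed constants)."""
    return SignatureModel(
        pairs=[
            ("AC099850.4", "MIR4435-2HG"),
            ("AC048341.2", "LENG8-AS1"),
            ("AC048341.2", "GIHCG"),
            ("AC048341.2", "LINC01436"),
            ("MIR4435-2HG", "AC110285.2"),
        ],
        coefficients=[0.3776, -0.3176, -0.3402, -0.3572, 0.4547],
        lambda_=None,
        provenance="published",
    )
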