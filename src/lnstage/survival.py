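"""Survival machinery: Kaplan–Meier, log-rank, Cox PH, log-rank power.

The Cox proportional-hazards fitter is implemented here directly: it
maximises the partial likelihood by Newton–Raphson with analytic gradient
and Hessian, using the Efron approximation for tied event times by default
(Breslow available), declaring convergence when the relative change in the
partial log-likelihood falls below 1e-9, with a cap of 50 iterations and
step-halving on any likelihood decrease.  Wald 95% confidence intervals
are exp(beta +/- 1.959964 * SE).  Kaplan–Meier estimation and the
(Mantel–Cox) log-rank test are delegated to lifelines.

The base adjusted model uses six dichotomised covariates: age >= 70,
male sex, tumor size >= cohort median, poor differentiation (G3+G4),
advanced T stage (T3+T4), and rectal location.  The size median is always
computed on the analysis cohort at hand, before dichotomisation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import Cohort

logger = logging.getLogger("lnstage")

Z975 = 1.959964  # two-sided 95% normal quantile

__all__ = [
    "CoxFit",
    "KMCurve",
    "LogrankResult",
    "SurvivalError",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "encode_base_covariates",
    "fit_base_model",
    "logrank_power",
]


class SurvivalError(ValueError):
    """Degenerate input or failed fit in the survival machinery."""


# --------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: event times, survival, risk-set sizes."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # risk-set size just before each event time
    censor_times: np.ndarray   # observed censoring times (marks)


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censored subjects leave the risk set after their observed time; with no
    censoring the curve equals the empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise SurvivalError("empty input")
    if np.any(times <= 0):
        raise SurvivalError("all times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    # risk set just before t: subjects with observed time >= t
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    return KMCurve(
        times=event_times,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times, events, groups) -> LogrankResult:
    """Mantel–Cox log-rank test across two or more groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise SurvivalError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(labels) - 1,
        p_value=float(res.p_value),
    )


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Result of a partial-likelihood fit."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    iterations: int
    converged: bool
    n: int
    n_events: int
    ties: str
    dropped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """Risk score X @ beta for the fitted terms (higher = worse)."""
        return X[self.terms].to_numpy(dtype=float) @ self.coef

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )


def _partial_loglik_derivs(beta, X, times, events, ties):
    """Log partial likelihood, gradient and information (negative Hessian).

    Rows must be sorted by ascending time.  Handles tied event times by the
    Efron or Breslow approximation via suffix sums over the risk set.
    """
    n, p = X.shape
    # clip the linear predictor: keeps every intermediate finite under
    # monotone-likelihood divergence (the fit is flagged in that case)
    eta = np.clip(X @ beta, -200.0, 200.0)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # suffix sums: S0[i] = sum_{j >= i} w_j etc. (risk set of time[i])
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    i = 0
    while i < n:
        t = times[i]
        j = i
        while j < n and times[j] == t:
            j += 1
        dead = [k for k in range(i, j) if events[k] == 1]
        d = len(dead)
        if d > 0:
            xd = X[dead]
            loglik += eta[dead].sum()
            grad += xd.sum(axis=0)
            s0, s1, s2 = S0[i], S1[i], S2[i]
            if ties == "efron" and d > 1:
                t0 = w[dead].sum()
                t1 = wx[dead].sum(axis=0)
                t2 = wxx[dead].sum(axis=0)
                for l in range(d):
                    f = l / d
                    phi = s0 - f * t0
                    psi = s1 - f * t1
                    xi = s2 - f * t2
                    loglik -= np.log(phi)
                    grad -= psi / phi
                    info += xi / phi - np.outer(psi, psi) / phi**2
            else:  # breslow, or single event
                loglik -= d * np.log(s0)
                grad -= d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        i = j
    return loglik, grad, info


def cox_fit(
    X: pd.DataFrame,
    times,
    events,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Parameters
    ----------
    X : DataFrame
        Numeric design matrix (no intercept).  Zero-variance columns are
        dropped with a warning recorded on the fit.
    ties : {"efron", "breslow"}
        Tied-event-time approximation.
    tol : float
        Convergence on relative change of the partial log-likelihood.

    Monotone-likelihood situations (complete separation of a covariate) are
    flagged via ``converged=False`` and an entry in ``warnings``, never
    returned silently.
    """
    if ties not in ("efron", "breslow"):
        raise SurvivalError(f"unknown tie method {ties!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise SurvivalError("no events")

    X = X.copy()
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        logger.warning("dropping zero-variance column(s): %s", dropped)
        X = X.drop(columns=dropped)
    terms = list(X.columns)
    if not terms:
        raise SurvivalError("empty design matrix after dropping constant columns")

    order = np.argsort(times, kind="stable")
    Xs = X.to_numpy(dtype=float)[order]
    ts = times[order]
    es = events[order]

    p = Xs.shape[1]
    beta = np.zeros(p)
    ll_null, _, _ = _partial_loglik_derivs(beta, Xs, ts, es, ties)
    ll = ll_null
    converged = False
    warnings_list: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        _, grad, info = _partial_loglik_derivs(beta, Xs, ts, es, ties)
        if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(info))):
            warnings_list.append("non-finite derivatives; monotone likelihood suspected")
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            warnings_list.append("singular information matrix")
            break
        # step-halving if the likelihood would decrease
        new_beta, new_ll = beta + step, None
        for _ in range(30):
            new_ll, _, _ = _partial_loglik_derivs(new_beta, Xs, ts, es, ties)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-14:
                break
            step /= 2.0
            new_beta = beta + step
        rel = abs(new_ll - ll) / max(abs(new_ll), 1.0)
        beta, ll = new_beta, new_ll
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings_list.append(f"did not converge in {it} iterations")
    if np.any(np.abs(beta) > 10):
        converged = False
        warnings_list.append("monotone likelihood suspected (|coef| > 10)")

    _, _, info = _partial_loglik_derivs(beta, Xs, ts, es, ties)
    try:
        if not np.all(np.isfinite(info)):
            raise np.linalg.LinAlgError
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        warnings_list.append("singular information at optimum")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        hr = np.exp(beta)
        ci_low = np.exp(beta - Z975 * se)
        ci_high = np.exp(beta + Z975 * se)
    fit = CoxFit(
        terms=terms,
        coef=beta,
        se=se,
        cov=cov,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        loglik=float(ll),
        loglik_null=float(ll_null),
        iterations=it,
        converged=converged,
        n=len(ts),
        n_events=int(es.sum()),
        ties=ties,
        dropped=dropped,
        warnings=warnings_list,
    )
    if warnings_list:
        logger.warning("cox_fit: %s", "; ".join(warnings_list))
    return fit


def cox_score_test(times, events, x, ties: str = "breslow") -> LogrankResult:
    """Score test of the Cox model at beta = 0 for a single covariate.

    On tie-free data with a binary group indicator this is algebraically
    the two-group log-rank statistic; exposed as an internal cross-check.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(x, dtype=float).reshape(len(times), -1)
    order = np.argsort(times, kind="stable")
    _, grad, info = _partial_loglik_derivs(
        np.zeros(X.shape[1]), X[order], times[order], events[order], ties
    )
    chi2 = float(grad @ np.linalg.solve(info, grad))
    df = X.shape[1]
    return LogrankResult(chi2, df, float(stats.chi2.sf(chi2, df)))


# --------------------------------------------------------------------------
# Base adjusted model
# --------------------------------------------------------------------------

BASE_TERMS = ["age_ge70", "male", "size_ge_median", "grade_34", "t_34", "rectum"]


def encode_base_covariates(cohort: Cohort) -> tuple[pd.DataFrame, dict]:
    """Dichotomise the six base-model covariates.

    Returns the 0/1 design matrix and a metadata dict recording the tumor
    size median used (computed on this cohort, before dichotomisation).
    """
    df = cohort.df
    required = ("age", "sex", "size_mm", "grade", "t_cat", "location")
    missing = [c for c in required if c not in df.columns or df[c].isna().any()]
    if missing:
        raise SurvivalError(
            f"base covariates incomplete (impute first): {missing}"
        )
    size_median = float(df["size_mm"].median())
    X = pd.DataFrame(
        {
            "age_ge70": (df["age"] >= 70).astype(int),
            "male": (df["sex"] == "male").astype(int),
            "size_ge_median": (df["size_mm"] >= size_median).astype(int),
            "grade_34": df["grade"].isin(["G3", "G4"]).astype(int),
            "t_34": df["t_cat"].isin(["T3", "T4"]).astype(int),
            "rectum": (df["location"] == "rectum").astype(int),
        },
        index=df.index,
    )
    return X, {"size_median_mm": size_median}


def fit_base_model(cohort: Cohort, ties: str = "efron") -> CoxFit:
    """Fit the six-covariate adjusted base model on a cohort."""
    X, _meta = encode_base_covariates(cohort)
    return cox_fit(X, cohort.df["time_months"], cohort.df["event"], ties=ties)


# --------------------------------------------------------------------------
# Log-rank power / sample size
# --------------------------------------------------------------------------

def logrank_power(
    hr: float,
    alpha: float = 0.05,
    power: float = 0.90,
    allocation: float = 0.5,
    event_fraction: float | None = None,
) -> dict:
    """Required events (and total n) for a two-sided log-rank test.

    Schoenfeld events formula:
    ``D = (z_{1-alpha/2} + z_{1-beta})^2 / (p(1-p) (ln hr)^2)``, rounded up;
    ``total_n = D / event_fraction`` when an event fraction is supplied.
    """
    if hr == 1:
        raise SurvivalError("hr must differ from 1")
    if not (0 < alpha < 1 and 0 < power < 1 and 0 < allocation < 1):
        raise SurvivalError("alpha, power and allocation must lie in (0,1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    d_exact = (za + zb) ** 2 / (allocation * (1 - allocation) * np.log(hr) ** 2)
    out = {"events_exact": float(d_exact), "events": int(np.ceil(d_exact))}
    if event_fraction is not None:
        if not 0 < event_fraction <= 1:
            raise SurvivalError("event_fraction must lie in (0,1]")
        out["total_n"] = int(np.ceil(d_exact / event_fraction))
    return out
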