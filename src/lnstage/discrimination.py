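"""Model discrimination: Harrell's C, jackknife Delta-C, FDR, landmark AUC.

Harrell's concordance treats a pair of subjects as comparable when the
shorter observed time is an event (an event tied in time with a censoring
is compared against the censored subject, who is known to survive at least
as long; two events at exactly the same time are incomparable).  A pair is
concordant when the shorter-lived subject carries the *higher* risk score
— the orientation of a Cox linear predictor — and tied scores count 1/2.

Two fitted risk models on the same subjects are compared by
``delta_c = C_a - C_b`` with a leave-one-out (jackknife) variance:
``var = (n-1)/n * sum_i (d_i - dbar)^2`` over the n leave-one-out
differences ``d_i``, giving a normal-approximation CI and two-sided p.
The same machinery yields a jackknife CI for a single C.  Leave-one-out
values are computed exactly in O(n^2) by subtracting each subject's pair
contributions from the full-sample tallies.

The Benjamini–Hochberg step-up adjustment takes an explicit family size m
(the number of schemes compared against the N category within one
analysis), which may exceed the number of p-values passed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

Z975 = 1.959964


class DiscriminationError(ValueError):
    """Degenerate input to a discrimination statistic."""


@dataclass
class ConcordanceResult:
    c_index: float
    n_comparable: int          # comparable (ordered) pairs
    n_tied_score: int          # comparable pairs with tied scores
    se: float | None = None    # jackknife SE, if requested
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class DeltaCResult:
    delta_c: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float | None
    n: int
    note: str = ""


@dataclass
class LandmarkAUC:
    horizon: float
    auc: float
    n_cases: int
    n_controls: int
    n_excluded: int


# --------------------------------------------------------------------------
# Harrell's C
# --------------------------------------------------------------------------

def _pair_matrices(scores, times, events):
    """Comparability and concordance-credit matrices over ordered pairs.

    ``comp[i, j]`` is True when subject i fails observably before j;
    ``credit[i, j]`` is 1 if score_i > score_j, 0.5 on ties, else 0.
    Each unordered comparable pair contributes exactly one True cell.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int).astype(bool)
    if not (len(s) == len(t) == len(e)):
        raise DiscriminationError("scores, times, events must have equal length")
    T_i, T_j = t[:, None], t[None, :]
    E_i, E_j = e[:, None], e[None, :]
    comp = ((T_i < T_j) & E_i) | ((T_i == T_j) & E_i & ~E_j)
    np.fill_diagonal(comp, False)
    S_i, S_j = s[:, None], s[None, :]
    credit = np.where(S_i > S_j, 1.0, np.where(S_i == S_j, 0.5, 0.0))
    return comp, credit


def harrell_c(scores, times, events) -> ConcordanceResult:
    """Harrell's concordance index of a risk score under censoring."""
    comp, credit = _pair_matrices(scores, times, events)
    den = int(comp.sum())
    if den == 0:
        raise DiscriminationError("no comparable pairs")
    num = float((comp * credit).sum())
    s = np.asarray(scores, dtype=float)
    ties = int((comp & (s[:, None] == s[None, :])).sum())
    return ConcordanceResult(c_index=num / den, n_comparable=den, n_tied_score=ties)


def _loo_concordance(scores, times, events) -> tuple[float, np.ndarray]:
    """Full-sample C and the vector of exact leave-one-out C values."""
    comp, credit = _pair_matrices(scores, times, events)
    num_mat = comp * credit
    Num, Den = float(num_mat.sum()), float(comp.sum())
    if Den == 0:
        raise DiscriminationError("no comparable pairs")
    num_k = num_mat.sum(axis=1) + num_mat.sum(axis=0)
    den_k = comp.sum(axis=1) + comp.sum(axis=0)
    loo_den = Den - den_k
    if np.any(loo_den == 0):
        raise DiscriminationError("a leave-one-out sample has no comparable pairs")
    return Num / Den, (Num - num_k) / loo_den


def _jackknife_se(values: np.ndarray) -> float:
    n = len(values)
    return float(np.sqrt((n - 1) / n * np.sum((values - values.mean()) ** 2)))


def harrell_c_ci(scores, times, events) -> ConcordanceResult:
    """Harrell's C with a jackknife (leave-one-out) SE and 95% CI."""
    res = harrell_c(scores, times, events)
    c, loo = _loo_concordance(scores, times, events)
    se = _jackknife_se(loo)
    res.se = se
    res.ci_low = c - Z975 * se
    res.ci_high = c + Z975 * se
    return res


def jackknife_delta_c(scores_a, scores_b, times, events) -> DeltaCResult:
    """Paired difference of two C statistics with jackknife inference.

    Both score vectors must be evaluated on the same subjects.  Returns
    ``delta_c = C_a - C_b``, its jackknife SE over leave-one-out
    differences, the normal 95% CI and a two-sided p.  Comparing a model
    with itself reports SE 0 and note ``"identical"``; SE 0 with a
    nonzero delta is flagged ``"degenerate"``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    n = len(scores_a)
    if len(scores_b) != n:
        raise DiscriminationError("score vectors must cover the same subjects")
    if n < 3:
        raise DiscriminationError("need at least 3 subjects for the jackknife")
    c_a, loo_a = _loo_concordance(scores_a, times, events)
    c_b, loo_b = _loo_concordance(scores_b, times, events)
    delta = c_a - c_b
    d_loo = loo_a - loo_b
    se = _jackknife_se(d_loo)
    if se == 0.0:
        note = "identical" if delta == 0.0 else "degenerate"
        return DeltaCResult(delta, 0.0, delta, delta, None, n, note)
    p = float(2.0 * stats.norm.sf(abs(delta) / se))
    return DeltaCResult(
        delta_c=delta,
        se=se,
        ci_low=delta - Z975 * se,
        ci_high=delta + Z975 * se,
        p_value=p,
        n=n,
    )


# --------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# --------------------------------------------------------------------------

def fdr_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``m`` is the family size (defaults to ``len(p_values)``); it may be
    larger when some family members are reported elsewhere.  For sorted
    p-values, ``p~_(k) = min_{j >= k} p_(j) * m / j``, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise DiscriminationError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)):
        raise DiscriminationError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise DiscriminationError("family size m cannot be smaller than len(p)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


# --------------------------------------------------------------------------
# Landmark ROC AUC
# --------------------------------------------------------------------------

def landmark_auc(scores, times, events, horizon: float) -> LandmarkAUC:
    """AUC of a score for death by a fixed horizon.

    Cases are subjects who died at or before the horizon; controls are
    followed beyond it (event or not); subjects censored at or before the
    horizon are excluded.  The AUC is the Mann–Whitney probability that a
    case outscores a control, ties counting 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int).astype(bool)
    if horizon <= 0:
        raise DiscriminationError("horizon must be > 0")
    case = e & (t <= horizon)
    control = t > horizon
    excluded = ~case & ~control
    n1, n0 = int(case.sum()), int(control.sum())
    if n1 == 0 or n0 == 0:
        raise DiscriminationError("need at least one case and one control")
    pooled = np.concatenate([s[case], s[control]])
    ranks = stats.rankdata(pooled)  # midranks
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return LandmarkAUC(
        horizon=float(horizon),
        auc=float(u / (n1 * n0)),
        n_cases=n1,
        n_controls=n0,
        n_excluded=int(excluded.sum()),
    )


# --------------------------------------------------------------------------
# Spearman correlation
# --------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DiscriminationError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DiscriminationError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
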