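"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive each statistic from its definition
(pair enumeration, full leave-one-out recomputation, direct likelihood
maximisation) and never call the implementation paths they check.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lnstage import SimulationConfig, prepare_cohort, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=654), prepared for analysis."""
    prepared, tally = prepare_cohort(simulate_cohort(SimulationConfig(seed=101)))
    return prepared


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def brute_force_c(scores, times, events) -> float:
    """Harrell's C by explicit enumeration of all subject pairs.

    A pair is usable when the earlier observed time is an event (an event
    tied with a censoring compares against the censored subject; two
    events at the same time do not compare).  Concordance credit 1 when
    the earlier failure has the higher score, 1/2 on score ties.
    """
    s, t, e = map(np.asarray, (scores, times, events))
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (t[i] < t[j] and e[i] == 1) or (
                t[i] == t[j] and e[i] == 1 and e[j] == 0
            )
            if not usable:
                continue
            den += 1
            if s[i] > s[j]:
                num += 1
            elif s[i] == s[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def brute_force_delta_c(scores_a, scores_b, times, events):
    """Jackknife Delta-C by full recomputation of both C's per deletion."""
    scores_a, scores_b = np.asarray(scores_a), np.asarray(scores_b)
    times, events = np.asarray(times), np.asarray(events)
    n = len(times)
    delta = brute_force_c(scores_a, times, events) - brute_force_c(
        scores_b, times, events
    )
    d_loo = []
    for i in range(n):
        keep = np.arange(n) != i
        d_loo.append(
            brute_force_c(scores_a[keep], times[keep], events[keep])
            - brute_force_c(scores_b[keep], times[keep], events[keep])
        )
    d_loo = np.asarray(d_loo)
    var = (n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2)
    return delta, float(np.sqrt(var))


def partial_loglik_1d(beta, times, events, x):
    """Log partial likelihood for one covariate, tie-free data, from the
    textbook product over event times."""
    t, e, x = map(np.asarray, (times, events, x))
    ll = 0.0
    for i in np.where(e == 1)[0]:
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def random_survival_instance(rng, n, p_event=0.7, tie_free=True, score_levels=None):
    """A small random censored-survival dataset for oracle comparisons."""
    if tie_free:
        times = rng.permutation(np.arange(1, n + 1)).astype(float)
    else:
        times = rng.integers(1, max(2, n // 2) + 1, n).astype(float)
    events = (rng.random(n) < p_event).astype(int)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    if score_levels:
        scores = rng.integers(0, score_levels, n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, times, events
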