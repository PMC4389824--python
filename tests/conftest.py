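"""Shared fixtures: tiny worked datasets and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from coxdiag.core import Episode


@pytest.fixture
def worked_three_subjects():
    """Three subjects with enumerable risk sets and closed-form solution.

    A: (0,1] event, x=1; B: (0,2] event, x=0; C: (0,3] censored, x=1.
    The partial-likelihood score is  1/(2u+1) - u/(u+1)  with u = exp(beta),
    whose root is u = 1/sqrt(2), i.e. beta = -log(2)/2.  Schoenfeld
    residuals are +/-(sqrt(2)-1); martingale residuals (1/sqrt2, 0, -1/sqrt2).
    """
    episodes = [
        Episode("A", 0.0, 1.0, {"x": 1.0}, True),
        Episode("B", 0.0, 2.0, {"x": 0.0}, True),
        Episode("C", 0.0, 3.0, {"x": 1.0}, False),
    ]
    expected = {
        "beta": -0.5 * np.log(2.0),
        "schoenfeld": np.array([[np.sqrt(2) - 1.0], [-(np.sqrt(2) - 1.0)]]),
        "martingale": {"A": 1 / np.sqrt(2), "B": 0.0, "C": -1 / np.sqrt(2)},
    }
    return episodes, expected


@pytest.fixture
def four_subject_episodes():
    """Four subjects, two events, one binary covariate; no ties."""
    return [
        Episode("a", 0.0, 1.0, {"x": 1.0}, True),
        Episode("b", 0.0, 2.5, {"x": 0.0}, True),
        Episode("c", 0.0, 3.0, {"x": 1.0}, False),
        Episode("d", 0.0, 4.0, {"x": 0.0}, False),
    ]


def brute_force_cox_loglik(episodes, beta):
    """Direct evaluation of the Breslow partial likelihood from first
    principles (risk sets enumerated independently of the fitting engine)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    events = [(ep.stop, ep) for ep in episodes if ep.event_at_stop]
    ll = 0.0
    for t, ep in sorted(events, key=lambda p: p[0]):
        x_ev = np.array([list(ep.covariates.values())], dtype=float)[0]
        denom = 0.0
        for other in episodes:
            if other.start < t <= other.stop:
                xo = np.array(list(other.covariates.values()), dtype=float)
                denom += np.exp(float(beta @ xo))
        ll += float(beta @ x_ev) - np.log(denom)
    return ll


@pytest.fixture
def brute_force_loglik():
    return brute_force_cox_loglik


def random_survival_frame(rng, n=40, p_event=0.5):
    """Right-censored data with continuous times (no ties, no delayed entry)."""
    import pandas as pd

    T = rng.exponential(5.0, n)
    C = rng.exponential(5.0 / p_event * (1 - p_event), n) + 0.2
    t = np.minimum(T, C)
    e = T <= C
    if e.sum() < 3:  # ensure enough events for the diagnostics
        e[:3] = True
    return pd.DataFrame(
        {
            "duration": t,
            "event": e.astype(int),
            "x1": rng.binomial(1, 0.5, n).astype(float),
            "x2": rng.normal(0, 1, n),
        }
    )


def frame_to_episodes(df):
    return [
        Episode(
            f"s{i}",
            0.0,
            float(r.duration),
            {"x1": float(r.x1), "x2": float(r.x2)},
            bool(r.event),
        )
        for i, r in enumerate(df.itertuples(index=False))
    ]
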