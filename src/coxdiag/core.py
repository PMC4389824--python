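"""Counting-process Cox regression with left truncation and residual accessors.

This module holds the data model shared by every diagnostic in the package:

* :class:`CohortRecord` — one subject of a prospective cohort with delayed
  entry (age at enrolment), an exit age (event or censoring), and fixed
  covariates.
* :class:`MeasurementSeries` — repeated measurements of a time-varying
  exposure for one subject.
* :class:`Episode` — the standard counting-process representation: a
  half-open age interval ``(start, stop]`` on which the covariate vector is
  constant, with the event flag attached to the final interval.
* :class:`CoxFit` — a fitted partial-likelihood model together with the
  per-event quantities (Schoenfeld residuals, risk-set covariance
  contributions, baseline-hazard increments) that the proportional-hazards
  diagnostics consume.

The fitter is written directly against the counting-process likelihood so
that risk sets honour delayed entry (``start < t <= stop``) and so that
time-interaction designs (covariate values that depend on the event time,
as needed by the spline models in :mod:`coxdiag.rcs`) share one engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CohortRecord",
    "MeasurementSeries",
    "Episode",
    "CoxFit",
    "ConvergenceError",
    "DegenerateModelError",
    "exclude_left_censored",
    "expand_counting_process",
    "fit_cox",
    "martingale_residuals",
    "schoenfeld_residuals",
]


class ConvergenceError(RuntimeError):
    """Raised when Newton-Raphson fails to drive the score to zero."""


class DegenerateModelError(ValueError):
    """Raised for models with no information (constant covariate, no events)."""


@dataclass(frozen=True)
class CohortRecord:
    """One subject: delayed-entry age, exit age, outcome and fixed covariates.

    ``positive_at_first_visit`` marks subjects already event-positive when
    first observed (left-censored onset age); such subjects must also carry
    ``event=True`` and are removed by :func:`exclude_left_censored` before
    any model fitting.
    """

    subject_id: str
    entry_age: float
    exit_age: float
    event: bool
    positive_at_first_visit: bool = False
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.entry_age) or self.entry_age < 0:
            raise ValueError(f"{self.subject_id}: entry_age must be finite and >= 0")
        if not math.isfinite(self.exit_age) or self.exit_age <= self.entry_age:
            raise ValueError(f"{self.subject_id}: exit_age must exceed entry_age")
        if self.positive_at_first_visit and not self.event:
            raise ValueError(
                f"{self.subject_id}: positive_at_first_visit implies event"
            )
        for name, value in self.covariates.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"{self.subject_id}: covariate {name!r} not finite")


@dataclass(frozen=True)
class MeasurementSeries:
    """Repeated (age, value) observations of one time-varying covariate."""

    subject_id: str
    observations: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ages = [a for a, _ in self.observations]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"{self.subject_id}: measurement ages must strictly increase")
        if any(not math.isfinite(v) for _, v in self.observations):
            raise ValueError(f"{self.subject_id}: non-finite measurement value")

    @property
    def ages(self) -> np.ndarray:
        return np.array([a for a, _ in self.observations], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.observations], dtype=float)


@dataclass(frozen=True)
class Episode:
    """Counting-process interval ``(start, stop]`` with constant covariates."""

    subject_id: str
    start: float
    stop: float
    covariates: Mapping[str, float]
    event_at_stop: bool

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"{self.subject_id}: episode stop must exceed start")


def exclude_left_censored(
    records: Sequence[CohortRecord],
) -> tuple[list[CohortRecord], int]:
    """Drop subjects already event-positive at their first visit.

    Their onset age is unknown (left-censored), so they cannot contribute to
    an onset-age hazard model.  Returns the retained records in the original
    order together with the number removed.
    """
    retained = [r for r in records if not r.positive_at_first_visit]
    return retained, len(records) - len(retained)


def expand_counting_process(
    records: Sequence[CohortRecord],
    series: Mapping[str, MeasurementSeries] | None = None,
    covariate_name: str = "exposure",
    carry_rule: str = "locf",
) -> list[Episode]:
    """Expand subjects into counting-process episodes.

    With no measurement series every subject contributes the single episode
    ``(entry_age, exit_age]``.  With a series, the subject's follow-up is
    split at their own measurement ages and the exposure value is carried
    forward (LOCF) from the most recent measurement at or before each
    episode start.  Time before the first measurement contributes no risk:
    the subject enters the analysis at the first measurement age (or at
    entry, if measured earlier).
    """
    if carry_rule != "locf":
        raise ValueError("carry_rule must be 'locf'")
    if series is not None:
        known = {r.subject_id for r in records}
        missing = set(series) - known
        if missing:
            raise KeyError(f"measurement series for unknown subjects: {sorted(missing)}")

    episodes: list[Episode] = []
    for rec in records:
        fixed = dict(rec.covariates)
        if series is None or rec.subject_id not in series:
            if series is not None:
                # A time-varying analysis cannot include unmeasured subjects.
                continue
            episodes.append(
                Episode(rec.subject_id, rec.entry_age, rec.exit_age, fixed, rec.event)
            )
            continue
        ms = series[rec.subject_id]
        ages, values = ms.ages, ms.values
        if ages[0] > rec.exit_age:
            raise ValueError(f"{rec.subject_id}: no usable measurement before exit")
        start0 = max(rec.entry_age, float(ages[0]))
        if start0 >= rec.exit_age:
            # only measurement coincides with exit: no at-risk interval once
            # exposure-lagged entry is applied; subject contributes nothing
            continue
        cuts = [start0]
        cuts += [float(a) for a in ages if start0 < a < rec.exit_age]
        cuts.append(rec.exit_age)
        for lo, hi in zip(cuts, cuts[1:]):
            idx = int(np.searchsorted(ages, lo, side="right")) - 1
            cov = dict(fixed)
            cov[covariate_name] = float(values[idx])
            episodes.append(
                Episode(rec.subject_id, lo, hi, cov, rec.event and hi == rec.exit_age)
            )
    return episodes


# ---------------------------------------------------------------------------
# Partial-likelihood engine
# ---------------------------------------------------------------------------


@dataclass
class _EpisodeData:
    """Flat array view of a set of episodes for one model fit."""

    subject_ids: list[str]          # per episode
    subjects: list[str]             # distinct, insertion order
    subject_index: np.ndarray       # per episode -> index into subjects
    start: np.ndarray
    stop: np.ndarray
    event: np.ndarray               # bool per episode
    X: np.ndarray                   # episodes x base covariates
    covariate_names: tuple[str, ...]


def _episode_arrays(
    episodes: Sequence[Episode], covariate_names: Sequence[str] | None = None
) -> _EpisodeData:
    if not episodes:
        raise ValueError("no episodes")
    if covariate_names is None:
        covariate_names = list(episodes[0].covariates)
    subjects: list[str] = []
    index: dict[str, int] = {}
    sub_idx = np.empty(len(episodes), dtype=int)
    X = np.empty((len(episodes), len(covariate_names)))
    for i, ep in enumerate(episodes):
        if ep.subject_id not in index:
            index[ep.subject_id] = len(subjects)
            subjects.append(ep.subject_id)
        sub_idx[i] = index[ep.subject_id]
        for j, name in enumerate(covariate_names):
            try:
                X[i, j] = float(ep.covariates[name])
            except KeyError:
                raise KeyError(f"episode of {ep.subject_id} lacks covariate {name!r}")
    data = _EpisodeData(
        subject_ids=[ep.subject_id for ep in episodes],
        subjects=subjects,
        subject_index=sub_idx,
        start=np.array([ep.start for ep in episodes]),
        stop=np.array([ep.stop for ep in episodes]),
        event=np.array([ep.event_at_stop for ep in episodes], dtype=bool),
        X=X,
        covariate_names=tuple(covariate_names),
    )
    # Per-subject sanity: at most one event episode, and it must be the last.
    for s in range(len(subjects)):
        mask = sub_idx == s
        ev = data.event[mask]
        if ev.sum() > 1 or (ev.any() and not ev[np.argmax(data.stop[mask])]):
            raise ValueError(f"subject {subjects[s]}: event must be on the final episode")
    return data


@dataclass
class CoxFit:
    """A converged Cox partial-likelihood fit on counting-process data.

    Besides the usual estimates this object retains the per-event
    Schoenfeld residuals, the per-event risk-set covariance contributions
    (used by the resampling supremum test), and the Breslow baseline-hazard
    increments (used for martingale residuals), all ordered by event time.
    """

    covariate_names: tuple[str, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    ties: str
    converged: bool
    n_subjects: int
    n_events: int
    event_times: np.ndarray          # one entry per event, nondecreasing
    event_subject_ids: list[str]
    schoenfeld: np.ndarray           # n_events x p
    event_info: np.ndarray           # n_events x p x p
    distinct_times: np.ndarray
    n_at_risk: np.ndarray            # per distinct time
    n_events_at: np.ndarray          # per distinct time
    baseline_increments: np.ndarray  # Breslow dLambda0 per distinct time
    martingale: dict[str, float]
    score_at_solution: np.ndarray
    time_varying: bool               # any covariate varies within subject

    @property
    def hazard_ratios(self) -> dict[str, float]:
        return {n: float(np.exp(b)) for n, b in zip(self.covariate_names, self.coefficients)}

    def covariate_index(self, name: str) -> int:
        try:
            return self.covariate_names.index(name)
        except ValueError:
            raise KeyError(f"covariate {name!r} not in fit") from None


def _risk_structure(data: _EpisodeData):
    """Distinct event times with risk-set and event indices per time."""
    ev_stop = data.stop[data.event]
    if ev_stop.size == 0:
        raise DegenerateModelError("no events in data")
    distinct = np.unique(ev_stop)
    risk_sets, event_sets = [], []
    for t in distinct:
        rs = np.flatnonzero((data.start < t) & (t <= data.stop))
        ev = np.flatnonzero(data.event[rs] & (data.stop[rs] == t))
        risk_sets.append(rs)
        event_sets.append(ev)
    return distinct, risk_sets, event_sets


DesignBuilder = Callable[[int, np.ndarray], np.ndarray]
"""Maps (distinct-event-time index, risk-set episode indices) to a design block."""


def _loglik_score_info(beta, designs, event_sets, ties):
    p = beta.size
    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    for Xj, ev in zip(designs, event_sets):
        eta = Xj @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        d = len(ev)
        S0 = w.sum()
        S1 = w @ Xj
        S2 = (Xj * w[:, None]).T @ Xj
        ll += eta[ev].sum()
        U += Xj[ev].sum(axis=0)
        if ties == "breslow" or d == 1:
            xbar = S1 / S0
            ll -= d * math.log(S0)
            U -= d * xbar
            I += d * (S2 / S0 - np.outer(xbar, xbar))
        else:  # efron
            wd = w[ev]
            Xd = Xj[ev]
            S0d = wd.sum()
            S1d = wd @ Xd
            S2d = (Xd * wd[:, None]).T @ Xd
            for l in range(d):
                f = l / d
                S0l = S0 - f * S0d
                S1l = S1 - f * S1d
                xbar = S1l / S0l
                ll -= math.log(S0l)
                U -= xbar
                I += (S2 - f * S2d) / S0l - np.outer(xbar, xbar)
    return ll, U, I


def _newton_raphson(designs, event_sets, p, ties, tol=1e-8, max_iter=50):
    beta = np.zeros(p)
    ll, U, I = _loglik_score_info(beta, designs, event_sets, ties)
    for _ in range(max_iter):
        if np.max(np.abs(U)) < tol:
            return beta, ll, U, I
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            raise DegenerateModelError(
                "singular information matrix (constant covariate or no contrast)"
            )
        # step halving on likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, U_new, I_new = _loglik_score_info(cand, designs, event_sets, ties)
            if math.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            raise ConvergenceError("step halving failed to improve likelihood")
        beta, ll, U, I = cand, ll_new, U_new, I_new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError("nonconvergence: infinite estimate")
    if np.max(np.abs(U)) < 1e-6:
        return beta, ll, U, I
    raise ConvergenceError(f"Newton-Raphson did not converge (|score|={np.max(np.abs(U)):.3g})")


def _fit_engine(
    data: _EpisodeData,
    design: DesignBuilder,
    names: tuple[str, ...],
    ties: str,
) -> CoxFit:
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    distinct, risk_sets, event_sets = _risk_structure(data)
    designs = [design(j, rs) for j, rs in enumerate(risk_sets)]
    p = designs[0].shape[1]
    # degenerate covariates: constant across every risk-set row
    allrows = np.vstack(designs)
    if np.any(np.ptp(allrows, axis=0) == 0):
        raise DegenerateModelError("covariate constant across all risk sets")
    beta, ll, U, I = _newton_raphson(designs, event_sets, p, ties)
    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        raise DegenerateModelError("singular information at solution")
    # monotone likelihood: the score can vanish numerically while the
    # estimate runs off to infinity; flag per-SD estimates beyond e^8
    col_sd = allrows.std(axis=0)
    if np.any(np.abs(beta) * col_sd > 8.0):
        raise ConvergenceError("nonconvergence: infinite estimate")
    cov = (cov + cov.T) / 2.0

    # Per-event quantities at the solution, ordered by event time.
    ev_times: list[float] = []
    ev_subjects: list[str] = []
    schoen: list[np.ndarray] = []
    einfo: list[np.ndarray] = []
    dL0 = np.empty(distinct.size)
    n_at_risk = np.empty(distinct.size, dtype=int)
    d_at = np.empty(distinct.size, dtype=int)
    accrual = np.zeros(len(data.subjects))
    for j, (t, rs, ev) in enumerate(zip(distinct, risk_sets, event_sets)):
        Xj = designs[j]
        w = np.exp(np.clip(Xj @ beta, -500, 500))
        d = len(ev)
        S0 = w.sum()
        S1 = w @ Xj
        S2 = (Xj * w[:, None]).T @ Xj
        n_at_risk[j] = len(rs)
        d_at[j] = d
        dL0[j] = d / S0
        np.add.at(accrual, data.subject_index[rs], w * dL0[j])
        if ties == "breslow" or d == 1:
            xbar = S1 / S0
            V = S2 / S0 - np.outer(xbar, xbar)
            for i in ev:
                ev_times.append(float(t))
                ev_subjects.append(data.subject_ids[rs[i]])
                schoen.append(Xj[i] - xbar)
                einfo.append(V)
        else:  # efron: l-th tied event uses the deflated risk-set mean
            wd = w[ev]
            Xd = Xj[ev]
            S0d = wd.sum()
            S1d = wd @ Xd
            S2d = (Xd * wd[:, None]).T @ Xd
            for l, i in enumerate(ev):
                f = l / d
                S0l = S0 - f * S0d
                S1l = S1 - f * S1d
                xbar = S1l / S0l
                ev_times.append(float(t))
                ev_subjects.append(data.subject_ids[rs[i]])
                schoen.append(Xj[i] - xbar)
                einfo.append((S2 - f * S2d) / S0l - np.outer(xbar, xbar))

    events_per_subject = np.zeros(len(data.subjects))
    np.add.at(events_per_subject, data.subject_index[data.event], 1.0)
    mart = {
        s: float(events_per_subject[k] - accrual[k])
        for k, s in enumerate(data.subjects)
    }

    tv = False
    for k in range(len(data.subjects)):
        rows = data.X[data.subject_index == k]
        if rows.shape[0] > 1 and np.any(np.ptp(rows, axis=0) > 0):
            tv = True
            break

    return CoxFit(
        covariate_names=names,
        coefficients=beta,
        covariance=cov,
        loglik=ll,
        ties=ties,
        converged=True,
        n_subjects=len(data.subjects),
        n_events=len(ev_times),
        event_times=np.array(ev_times),
        event_subject_ids=ev_subjects,
        schoenfeld=np.array(schoen),
        event_info=np.array(einfo),
        distinct_times=distinct,
        n_at_risk=n_at_risk,
        n_events_at=d_at,
        baseline_increments=dL0,
        martingale=mart,
        score_at_solution=U,
        time_varying=tv,
    )


def fit_cox(
    episodes: Sequence[Episode],
    covariate_names: Sequence[str] | None = None,
    ties: str = "breslow",
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on counting-process episodes.

    Risk sets are left-truncation aware: an episode is at risk at event time
    ``t`` iff ``start < t <= stop``.  Convergence requires the score norm to
    fall below 1e-8 (50 iterations with step halving); failure raises
    :class:`ConvergenceError` rather than returning a bad fit.
    """
    data = _episode_arrays(episodes, covariate_names)
    design: DesignBuilder = lambda j, rs: data.X[rs]
    return _fit_engine(data, design, data.covariate_names, ties)


def martingale_residuals(fit: CoxFit) -> dict[str, float]:
    """Per-subject martingale residuals: observed events minus accrued
    cumulative hazard under the Breslow baseline.  They sum to zero."""
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    return dict(fit.martingale)


def schoenfeld_residuals(fit: CoxFit) -> np.ndarray:
    """Per-event Schoenfeld residual matrix (events x covariates), ordered by
    event time: the event subject's covariate values minus the risk-set
    weighted mean.  Columns sum to zero at the solution."""
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    return fit.schoenfeld.copy()
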