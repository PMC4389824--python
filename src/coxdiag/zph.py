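"""Scaled Schoenfeld residual tests of proportional hazards.

Implements the Grambsch-Therneau construction: each event's Schoenfeld
residual vector, scaled by (number of events) times the coefficient
covariance and offset by the estimate, approximates the time-varying
coefficient beta(t) at that event time.  A zero-slope score test of the
scaled residuals against a transform of event time gives a one-degree-of-
freedom chi-square per covariate and a global test across all covariates.

Conventions follow the classic implementation contemporaneous with the
screening workflow this package supports: the default time transform is
``km`` (one minus the left-continuous Kaplan-Meier estimate at each event
time) and the risk-set covariance is approximated by the average
information, so the per-covariate statistic is

    chi_j = m * (V u)_j^2 / (V_jj * sum((g - gbar)^2))

with ``u`` the transform-weighted residual sum, ``V`` the coefficient
covariance and ``m`` the event count; the global statistic is
``m * u' V u / sum((g - gbar)^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ConvergenceError, CoxFit

__all__ = [
    "ZphResult",
    "scaled_schoenfeld",
    "zph_test",
    "interpret_zph",
    "smooth_beta_t",
]

TRANSFORMS = ("km", "identity", "rank", "log")


@dataclass
class ZphResult:
    """Per-covariate and global zero-slope tests plus smoothed beta(t)."""

    covariate_names: tuple[str, ...]
    statistics: np.ndarray          # per covariate chi-square, df=1
    p_values: np.ndarray
    global_statistic: float
    global_df: int
    global_p: float
    time_transform: str
    event_times: np.ndarray
    transformed_times: np.ndarray
    scaled_residuals: np.ndarray    # events x covariates
    curves: dict[str, np.ndarray] = field(default_factory=dict)
    reliability_warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "transform": self.time_transform,
            "global": {
                "statistic": float(self.global_statistic),
                "df": self.global_df,
                "p": float(self.global_p),
            },
            "individual": {
                name: {"statistic": float(s), "df": 1, "p": float(p)}
                for name, s, p in zip(self.covariate_names, self.statistics, self.p_values)
            },
            "reliability_warnings": list(self.reliability_warnings),
        }

    def curve_to_csv(self, covariate: str, path) -> None:
        """Write a covariate's smoothed beta(t) curve as CSV
        (time, beta, lower, upper)."""
        np.savetxt(
            path, self.curves[covariate], delimiter=",",
            header="time,beta,lower,upper", comments="",
        )


def scaled_schoenfeld(fit: CoxFit) -> np.ndarray:
    """Scaled Schoenfeld residuals: ``beta_hat + m * s_k @ V``.

    Each row approximates the time-varying coefficient at that event time;
    the column means equal the fitted coefficients.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    return fit.coefficients + fit.n_events * (fit.schoenfeld @ fit.covariance)


def _transform_times(fit: CoxFit, transform: str) -> np.ndarray:
    """Transformed event times, one entry per event (ties share a value)."""
    t = fit.event_times
    if transform == "identity":
        return t.astype(float)
    if transform == "log":
        if np.any(t <= 0):
            raise ValueError("log transform requires positive event times")
        return np.log(t)
    if transform == "rank":
        return stats.rankdata(t)
    if transform == "km":
        # Left-continuous KM from the fit's own risk sets (delayed-entry aware):
        # events at the j-th distinct time get 1 - S(t_{j-1}), with S(t_0) = 1.
        surv = np.cumprod(1.0 - fit.n_events_at / fit.n_at_risk)
        prior = np.concatenate([[1.0], surv[:-1]])
        g = 1.0 - prior
        return np.repeat(g, fit.n_events_at)
    raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


def _variance_ratio_warnings(fit: CoxFit, var_ratio: float) -> tuple[str, ...]:
    """Flag time-varying covariates whose risk-set variance drifts over time.

    The zero-slope test assumes that variance is stable; when the mean
    per-event risk-set variance differs across time terciles by more than
    ``var_ratio``, the result for that covariate is marked unreliable.
    """
    if not fit.time_varying:
        return ()
    m = fit.n_events
    if m < 6:
        return ()
    variances = np.diagonal(fit.event_info, axis1=1, axis2=2)  # m x p
    order = np.argsort(fit.event_times, kind="stable")
    terciles = np.array_split(order, 3)
    flagged = []
    for j, name in enumerate(fit.covariate_names):
        means = [float(np.mean(variances[idx, j])) for idx in terciles]
        lo, hi = min(means), max(means)
        if lo <= 0 or hi / lo > var_ratio:
            flagged.append(name)
    return tuple(flagged)


def zph_test(
    fit: CoxFit,
    transform: str = "km",
    span: float = 0.75,
    var_ratio: float = 4.0,
    with_curves: bool = True,
) -> ZphResult:
    """Zero-slope score test of scaled Schoenfeld residuals vs time.

    Returns per-covariate 1-df chi-square tests, a global test with df equal
    to the number of covariates, the scaled residuals, and (optionally) a
    local-linear smooth of beta(t) with a pointwise +/- 2 SE band per
    covariate.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    m = fit.n_events
    if m < 3:
        raise ValueError("insufficient events for slope test (need >= 3)")
    g = _transform_times(fit, transform)
    xx = g - g.mean()
    ssg = float(xx @ xx)
    if ssg <= 1e-12 * max(1.0, float(np.abs(g).max()) ** 2):
        raise ValueError("degenerate time transform: no variance in transformed times")

    V = fit.covariance
    u = xx @ fit.schoenfeld                    # p-vector
    Vu = V @ u
    per_cov = m * Vu**2 / (np.diag(V) * ssg)
    per_p = stats.chi2.sf(per_cov, 1)
    global_stat = float(m * (u @ Vu) / ssg)
    p_global = float(stats.chi2.sf(global_stat, len(u)))

    scaled = scaled_schoenfeld(fit)
    curves: dict[str, np.ndarray] = {}
    if with_curves:
        for j, name in enumerate(fit.covariate_names):
            curves[name] = smooth_beta_t(scaled[:, j], fit.event_times, span=span)

    return ZphResult(
        covariate_names=fit.covariate_names,
        statistics=per_cov,
        p_values=per_p,
        global_statistic=global_stat,
        global_df=len(u),
        global_p=p_global,
        time_transform=transform,
        event_times=fit.event_times.copy(),
        transformed_times=g,
        scaled_residuals=scaled,
        curves=curves,
        reliability_warnings=_variance_ratio_warnings(fit, var_ratio),
    )


def interpret_zph(result: ZphResult, threshold: float = 0.30) -> tuple[str, ...]:
    """Gated screening: individual tests are consulted only when the global
    test is small.  Returns the names of flagged covariates (empty when the
    global p is at or above the threshold)."""
    if result.global_p >= threshold:
        return ()
    return tuple(
        name
        for name, p in zip(result.covariate_names, result.p_values)
        if p < threshold
    )


def smooth_beta_t(
    residuals: np.ndarray,
    times: np.ndarray,
    span: float = 0.75,
    eval_times: np.ndarray | None = None,
) -> np.ndarray:
    """Local-linear (loess-style, tricube weights) smooth of scaled residuals.

    Returns an array of (time, beta, lower, upper) rows where the band is
    the pointwise fit +/- 2 standard errors.  Exact on data that are exactly
    linear in time.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    y = np.asarray(residuals, dtype=float)
    t = np.asarray(times, dtype=float)
    if eval_times is None:
        eval_times = np.unique(t)
    n = t.size
    k = max(3, int(np.ceil(span * n)))
    k = min(k, n)

    out = np.empty((len(eval_times), 4))
    # residual-variance estimate from a first smoothing pass at the data points
    def _local_fit(x0: float):
        d = np.abs(t - x0)
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
        sw = w.sum()
        tb = (w @ t) / sw
        yb = (w @ y) / sw
        stt = w @ (t - tb) ** 2
        if stt < 1e-12 * max(1.0, tb * tb):
            slope = 0.0
        else:
            slope = (w @ ((t - tb) * (y - yb))) / stt
        # equivalent-kernel vector for variance of the fitted value
        if stt < 1e-12 * max(1.0, tb * tb):
            l = w / sw
        else:
            l = w / sw + (x0 - tb) * w * (t - tb) / stt
        return yb + slope * (x0 - tb), float(l @ l)

    fitted_at_data = np.array([_local_fit(x)[0] for x in t])
    dof = max(n - 2, 1)
    sigma2 = float(np.sum((y - fitted_at_data) ** 2) / dof)
    for i, x0 in enumerate(eval_times):
        yhat, ll = _local_fit(float(x0))
        se = np.sqrt(sigma2 * ll)
        out[i] = (x0, yhat, yhat - 2 * se, yhat + 2 * se)
    return out
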