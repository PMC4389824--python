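"""Restricted-cubic-spline time-interaction Cox models.

The hazard-ratio-versus-time curve for a covariate x is modelled by letting
its log hazard ratio vary with age,

    h(t | x, z) = h0(t) * exp(gamma' z + beta(t) * x),
    beta(t) = theta_0 + theta_1 * t + sum_j theta_{j+1} * b_j(t),

where the b_j are restricted cubic basis terms (piecewise cubic, continuous
through second derivatives at the knots, linear beyond the boundary knots).
In the partial likelihood the interaction columns are evaluated at each
event time against the episodes then at risk, which makes the construction
equally valid for time-varying covariates: the current covariate value is
multiplied by the basis at the event time.

Three Wald tests are performed hierarchically for a k-knot model:
association (all k interaction parameters, k df), nonconstancy (the k-1
time-dependent parameters, k-1 df; a rejection means the hazard ratio is
not constant), and nonlinearity (the k-2 curved parameters, k-2 df).  Each
later test is performed only when the earlier null was rejected, unless
gating is disabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .core import (
    ConvergenceError,
    CoxFit,
    DegenerateModelError,
    Episode,
    _episode_arrays,
    _fit_engine,
)

__all__ = [
    "RcsBasis",
    "RcsFit",
    "HierarchicalTests",
    "place_knots",
    "rcs_basis_eval",
    "fit_rcs_cox",
    "hierarchical_tests",
    "select_knots_by_aic",
    "hr_curve",
]


@dataclass(frozen=True)
class RcsBasis:
    """Restricted cubic spline basis: k >= 3 strictly increasing knots.

    The basis has dimension k - 1: the linear term plus k - 2 restricted
    truncated-cubic terms, each divided by (last knot - first knot)^2 so all
    terms share comparable magnitude.  Any fixed positive scale yields an
    equivalent model (tests and curves are invariant); ``scale_override``
    exists to make that property checkable.
    """

    knots: tuple[float, ...]
    scale_override: float | None = None

    def __post_init__(self) -> None:
        if len(self.knots) < 3:
            raise ValueError("need at least 3 knots")
        if any(b <= a for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError("knots must be strictly increasing")
        if self.scale_override is not None and self.scale_override <= 0:
            raise ValueError("scale must be positive")

    @property
    def k(self) -> int:
        return len(self.knots)

    @property
    def scale(self) -> float:
        if self.scale_override is not None:
            return self.scale_override
        return (self.knots[-1] - self.knots[0]) ** 2

    @property
    def dim(self) -> int:
        return self.k - 1


def place_knots(
    event_ages: Sequence[float],
    k: int = 3,
    percentiles: Sequence[float] | None = None,
) -> RcsBasis:
    """Knots at empirical percentiles of the event ages (cases only).

    Defaults to 3 knots at the 5th, 50th and 95th percentiles, the sparse
    placement appropriate when events are few.  Percentile computation uses
    linear interpolation between order statistics.
    """
    ages = np.asarray(event_ages, dtype=float)
    if percentiles is None:
        if k == 3:
            percentiles = (5.0, 50.0, 95.0)
        else:
            # Harrell's conventional outer percentiles for k knots
            outer = {4: (5.0, 95.0), 5: (5.0, 95.0), 6: (5.0, 95.0), 7: (2.5, 97.5)}.get(
                k, (5.0, 95.0)
            )
            percentiles = tuple(np.linspace(outer[0], outer[1], k))
    if len(percentiles) != k:
        raise ValueError("need exactly k percentiles")
    if np.unique(ages).size < k:
        raise ValueError(f"need at least {k} distinct event ages")
    knots = np.percentile(ages, percentiles, method="linear")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate event-age distribution: duplicate knots")
    return RcsBasis(tuple(float(x) for x in knots))


def rcs_basis_eval(t, basis: RcsBasis) -> np.ndarray:
    """Evaluate the spline basis at age(s) t.

    Returns the k-1 basis values [t, b_1(t), ..., b_{k-2}(t)] (last axis for
    array input).  Each b_j is the restricted truncated-power cubic

        b_j(t) = [ (t-K_j)+^3 - (t-K_{k-1})+^3 (K_k-K_j)/(K_k-K_{k-1})
                   + (t-K_k)+^3 (K_{k-1}-K_j)/(K_k-K_{k-1}) ] / (K_k-K_1)^2,

    which is linear beyond the boundary knots.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    K = np.asarray(basis.knots)
    k = basis.k
    tau = basis.scale
    out = np.empty(t.shape + (k - 1,))
    out[..., 0] = t

    def plus3(x):
        return np.clip(x, 0.0, None) ** 3

    denom = K[-1] - K[-2]
    for j in range(k - 2):
        out[..., j + 1] = (
            plus3(t - K[j])
            - plus3(t - K[-2]) * (K[-1] - K[j]) / denom
            + plus3(t - K[-1]) * (K[-2] - K[j]) / denom
        ) / tau
    return out


@dataclass
class RcsFit:
    """A fitted spline time-interaction Cox model.

    ``theta`` holds the k interaction coefficients (constant, linear,
    curved...); ``beta_t`` and :func:`hr_curve` evaluate the fitted
    log-hazard-ratio curve and its confidence band for a covariate contrast
    of ``delta`` units.
    """

    covariate: str
    adjustment: tuple[str, ...]
    basis: RcsBasis
    delta: float
    fit: CoxFit
    theta_index: np.ndarray       # indices of theta within the coefficient vector
    time_varying_extension: bool
    _refit: "Callable[[int], CoxFit] | None" = None          # nested-model refitter
    _nested_loglik: "Callable[[int], float] | None" = None   # loglik of nested models

    @property
    def theta(self) -> np.ndarray:
        return self.fit.coefficients[self.theta_index]

    @property
    def theta_covariance(self) -> np.ndarray:
        return self.fit.covariance[np.ix_(self.theta_index, self.theta_index)]

    @property
    def adjustment_coefficients(self) -> dict[str, float]:
        return {
            name: float(self.fit.coefficients[i])
            for i, name in enumerate(self.adjustment)
        }

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def aic(self) -> float:
        return -2.0 * self.fit.loglik + 2.0 * self.fit.coefficients.size

    def time_basis(self, t) -> np.ndarray:
        """Row(s) [1, t, b_1(t), ...] multiplying theta in beta(t)."""
        b = rcs_basis_eval(t, self.basis)
        ones = np.ones(b.shape[:-1] + (1,))
        return np.concatenate([ones, b], axis=-1)

    def beta_t(self, t) -> np.ndarray:
        """Fitted per-unit log hazard ratio beta(t)."""
        return self.time_basis(t) @ self.theta

    def beta_t_se(self, t) -> np.ndarray:
        c = self.time_basis(t)
        V = self.theta_covariance
        return np.sqrt(np.einsum("...i,ij,...j->...", c, V, c))


def fit_rcs_cox(
    episodes: Sequence[Episode],
    covariate: str,
    adjustment: Sequence[str] = (),
    basis: RcsBasis | None = None,
    delta: float = 1.0,
    ties: str = "breslow",
    knots_k: int = 3,
) -> RcsFit:
    """Fit the spline time-interaction model for one covariate.

    ``delta`` is the covariate contrast (in covariate units) used when the
    curve is reported as a hazard ratio; the fit itself is per unit.  When
    ``basis`` is omitted, knots are placed from the event ages of the data.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    data = _episode_arrays(episodes, list(adjustment) + [covariate])
    n_adj = len(adjustment)
    x_col = n_adj

    if basis is None:
        ev_ages = data.stop[data.event]
        basis = place_knots(ev_ages, k=knots_k)
    follow_lo, follow_hi = float(data.start.min()), float(data.stop.max())
    if basis.knots[0] < follow_lo or basis.knots[-1] > follow_hi:
        raise ValueError("basis knots outside follow-up range")

    ev_stop = np.unique(data.stop[data.event])
    C = np.empty((ev_stop.size, basis.k))
    C[:, 0] = 1.0
    C[:, 1:] = rcs_basis_eval(ev_stop, basis)

    all_names = tuple(adjustment) + tuple(
        [covariate, f"{covariate}:t"]
        + [f"{covariate}:rcs{j}" for j in range(1, basis.k - 1)]
    )

    def fit_nested(n_time: int) -> CoxFit:
        """Fit with the first ``n_time`` interaction columns (0..k)."""

        def design(j: int, rs: np.ndarray) -> np.ndarray:
            parts = []
            if n_adj:
                parts.append(data.X[rs, :n_adj])
            if n_time:
                x = data.X[rs, x_col]
                parts.append(x[:, None] * C[j][None, :n_time])
            if not parts:
                # adjustment-free null model: a zero-information dummy is not
                # usable; compute the empty-model log likelihood directly
                raise ValueError("empty design")
            return np.hstack(parts) if len(parts) > 1 else parts[0]

        names = tuple(adjustment) + all_names[n_adj : n_adj + n_time]
        return _fit_engine(data, design, names, ties)

    def nested_loglik(n_time: int) -> float:
        if n_time == 0 and n_adj == 0:
            return _null_loglik_data(data, ties)
        return fit_nested(n_time).loglik

    fit = fit_nested(basis.k)
    return RcsFit(
        covariate=covariate,
        adjustment=tuple(adjustment),
        basis=basis,
        delta=float(delta),
        fit=fit,
        theta_index=np.arange(n_adj, n_adj + basis.k),
        time_varying_extension=bool(fit.time_varying),
        _refit=fit_nested,
        _nested_loglik=nested_loglik,
    )


def _null_loglik_data(data, ties: str) -> float:
    """Log partial likelihood of the covariate-free model (all betas absent)."""
    from .core import _risk_structure

    _, risk_sets, event_sets = _risk_structure(data)
    ll = 0.0
    for rs, ev in zip(risk_sets, event_sets):
        d = len(ev)
        nr = len(rs)
        if ties == "breslow" or d == 1:
            ll -= d * np.log(nr)
        else:  # efron with unit weights: deflated risk-set sizes nr - l
            for l in range(d):
                ll -= np.log(nr - l)
    return ll


def null_loglik(episodes: Sequence[Episode], ties: str = "breslow") -> float:
    """Log partial likelihood of the model with no covariates at all."""
    return _null_loglik_data(_episode_arrays(episodes, []), ties)


@dataclass
class HierarchicalTests:
    """Association / nonconstancy / nonlinearity Wald tests, gated in order."""

    association: tuple[float, int, float]
    nonconstant: tuple[float, int, float] | None
    nonlinear: tuple[float, int, float] | None
    alpha: float
    gated: bool

    def to_dict(self) -> dict:
        def cell(t):
            if t is None:
                return {"p": None, "na_reason": "gated"}
            s, df, p = t
            return {"statistic": float(s), "df": int(df), "p": float(p)}

        return {
            "association": cell(self.association),
            "nonconstant": cell(self.nonconstant),
            "nonlinear": cell(self.nonlinear),
        }


def _wald(theta: np.ndarray, V: np.ndarray) -> tuple[float, int, float]:
    stat = float(theta @ np.linalg.solve(V, theta))
    df = theta.size
    return stat, df, float(stats.chi2.sf(stat, df))


def hierarchical_tests(
    rcsfit: RcsFit, alpha: float = 0.05, gate: bool = True, method: str = "wald"
) -> HierarchicalTests:
    """Tests of the interaction parameters, performed hierarchically.

    For k knots: association tests all k parameters (is the covariate
    associated with the event at any age, k df); nonconstancy tests the k-1
    time-dependent parameters (is the hazard ratio constant — the
    proportional-hazards test, k-1 df); nonlinearity tests the k-2 curved
    parameters (k-2 df).  With ``gate=True`` (default) a later test is
    performed only if the previous null was rejected at ``alpha``; with
    ``gate=False`` all three are computed.

    ``method`` selects Wald quadratic forms (default, the convention of the
    spline macro family this workflow follows) or likelihood-ratio tests
    (``"lr"``; each reduced model is refitted).  The two agree
    asymptotically but can differ at modest event counts because the
    time-interaction columns of a 3-knot spline are strongly collinear over
    a bounded follow-up window.
    """
    theta = rcsfit.theta
    V = rcsfit.theta_covariance
    if not np.all(np.isfinite(V)):
        raise ValueError("missing or non-finite covariance")
    k = rcsfit.basis.k

    if method == "wald":
        association = _wald(theta, V)
        make_nonconstant = lambda: _wald(theta[1:], V[1:, 1:])
        make_nonlinear = lambda: _wald(theta[2:], V[2:, 2:])
    elif method == "lr":
        if rcsfit._nested_loglik is None:
            raise ValueError("likelihood-ratio tests need the fitted model context")
        ll_full = rcsfit.loglik

        def _lr(n_time: int, df: int) -> tuple[float, int, float]:
            stat = max(0.0, 2.0 * (ll_full - rcsfit._nested_loglik(n_time)))
            return stat, df, float(stats.chi2.sf(stat, df))

        association = _lr(0, k)
        make_nonconstant = lambda: _lr(1, k - 1)
        make_nonlinear = lambda: _lr(2, k - 2)
    else:
        raise ValueError("method must be 'lr' or 'wald'")

    nonconstant = nonlinear = None
    if not gate or association[2] < alpha:
        nonconstant = make_nonconstant()
        if not gate or nonconstant[2] < alpha:
            if theta.size > 2:
                nonlinear = make_nonlinear()
    return HierarchicalTests(
        association=association,
        nonconstant=nonconstant,
        nonlinear=nonlinear,
        alpha=alpha,
        gated=gate,
    )


def select_knots_by_aic(
    episodes: Sequence[Episode],
    covariate: str,
    adjustment: Sequence[str] = (),
    candidate_k: Sequence[int] = (3, 4, 5),
    delta: float = 1.0,
    ties: str = "breslow",
) -> RcsFit:
    """Fit every candidate knot count and return the lowest-AIC model.

    Ties (and candidates that fail, e.g. for lack of distinct event ages)
    resolve toward fewer knots.
    """
    best: RcsFit | None = None
    last_err: Exception | None = None
    for k in sorted(candidate_k):
        try:
            cand = fit_rcs_cox(
                episodes, covariate, adjustment, basis=None, delta=delta, ties=ties,
                knots_k=k,
            )
        except (
            ValueError,
            DegenerateModelError,
            ConvergenceError,
            np.linalg.LinAlgError,
        ) as err:
            last_err = err
            continue
        if best is None or cand.aic < best.aic:
            best = cand
    if best is None:
        raise last_err if last_err is not None else ValueError("no candidates")
    return best


def hr_curve(
    rcsfit: RcsFit,
    grid_ages: Sequence[float],
    ci_level: float = 0.95,
) -> np.ndarray:
    """Hazard-ratio curve HR(t) = exp(delta * beta(t)) with pointwise CI.

    Returns rows (age, hr, lower, upper, extrapolated).  The band is the
    delta-method interval on the linear predictor, exponentiated.  Ages
    outside the fitted follow-up range are extrapolated linearly (the spline
    is linear in its tails) and flagged.
    """
    ages = np.asarray(grid_ages, dtype=float)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    est = rcsfit.delta * rcsfit.beta_t(ages)
    se = rcsfit.delta * rcsfit.beta_t_se(ages)
    lo_t = float(rcsfit.fit.event_times.min())
    hi_t = float(rcsfit.fit.event_times.max())
    extrap = (ages < lo_t) | (ages > hi_t)
    if np.any(extrap):
        import warnings

        warnings.warn(
            "grid ages outside the event-time range are linear extrapolations",
            stacklevel=2,
        )
    return np.column_stack(
        [ages, np.exp(est), np.exp(est - z * se), np.exp(est + z * se), extrap]
    )
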