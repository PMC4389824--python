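"""Resampling supremum test for proportional hazards.

The observed cumulative score process for a covariate — the running sum of
its Schoenfeld residuals over event times, standardised by ``n**-0.5`` —
fluctuates around zero when the hazard ratio is constant and drifts when it
is not.  Its null distribution is approximated by multiplier (wild)
resampling: each event's full score contribution is perturbed by an
independent standard-normal multiplier and the resulting path is re-centred
through the cumulative observed information, so every simulated path also
terminates at zero.  The p-value is the fraction of simulated suprema (of
the absolute path) at least as large as the observed supremum.
"""

from __future__ import annotations

import secrets
from dataclasses import dataclass

import numpy as np

from .core import ConvergenceError, CoxFit

__all__ = ["SupremumResult", "score_process", "supremum_test", "interpret_supremum"]


@dataclass
class SupremumResult:
    """Outcome of the multiplier-resampling supremum test for one covariate."""

    covariate: str
    observed_path: np.ndarray      # (n_events, 2): event time, standardized score
    observed_sup: float
    n_paths: int
    p_value: float
    seed: int
    n_exceed: int
    simulated_sup: np.ndarray
    time_varying_extension: bool = False

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "observed_sup": self.observed_sup,
            "n_paths": self.n_paths,
            "seed": self.seed,
            "p_value": self.p_value,
            "time_varying_extension": self.time_varying_extension,
            "path": [[float(t), float(v)] for t, v in self.observed_path],
        }

    def path_to_csv(self, path) -> None:
        """Write the observed score path as two-column CSV (time, score)."""
        np.savetxt(
            path, self.observed_path, delimiter=",", header="time,score",
            comments="",
        )


def score_process(fit: CoxFit, covariate: str) -> np.ndarray:
    """Observed cumulative standardized score path for one covariate.

    Returns an array of (event time, value) pairs where the value at the
    j-th event is ``n**-0.5`` times the running sum of that covariate's
    Schoenfeld residuals.  The final value is zero (to numerical precision)
    because the residual columns sum to zero at the solution.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    k = fit.covariate_index(covariate)
    scale = 1.0 / np.sqrt(fit.n_subjects)
    values = np.cumsum(fit.schoenfeld[:, k]) * scale
    return np.column_stack([fit.event_times, values])


def supremum_test(
    fit: CoxFit,
    covariate: str,
    n_paths: int = 1000,
    seed: int | None = None,
) -> SupremumResult:
    """Multiplier-resampling supremum test of proportional hazards.

    ``n_paths`` defaults to 1000 simulated null paths.  ``seed`` is recorded
    in the result; if omitted a fresh one is drawn so the run remains
    reproducible after the fact.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if seed is None:
        seed = secrets.randbelow(2**31)
    k = fit.covariate_index(covariate)

    path = score_process(fit, covariate)
    observed_sup = float(np.max(np.abs(path[:, 1])))

    S = fit.schoenfeld                       # m x p score contributions
    m, p = S.shape
    Ccum = np.cumsum(fit.event_info, axis=0)  # m x p x p cumulative information
    I_total = Ccum[-1]
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n_paths, m))

    A = np.cumsum(G[:, :, None] * S[None, :, :], axis=1)   # paths x m x p
    B = A[:, -1, :]                                        # paths x p
    # re-centring term: C_k @ I^{-1} @ B for each event index k
    IinvB = np.linalg.solve(I_total, B.T).T                # paths x p
    corr = np.einsum("mpq,nq->nmp", Ccum, IinvB)           # paths x m x p
    W = (A - corr)[:, :, k] / np.sqrt(fit.n_subjects)      # paths x m
    sim_sup = np.max(np.abs(W), axis=1)

    n_exceed = int(np.sum(sim_sup >= observed_sup))
    return SupremumResult(
        covariate=covariate,
        observed_path=path,
        observed_sup=observed_sup,
        n_paths=n_paths,
        p_value=n_exceed / n_paths,
        seed=seed,
        n_exceed=n_exceed,
        simulated_sup=sim_sup,
        time_varying_extension=fit.time_varying,
    )


def interpret_supremum(p_value: float, threshold: float = 0.30) -> str:
    """Screening verdict: ``"violation"`` iff ``p_value < threshold``.

    The 0.30 default is a deliberately liberal screening convention for
    flagging candidate departures from proportional hazards; it is exposed
    as a parameter and not endorsed as a significance level.
    """
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("p_value must be in [0, 1]")
    return "violation" if p_value < threshold else "no-evidence"
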