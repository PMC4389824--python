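"""Simulation of prospective visit-based cohorts with age-varying effects.

The generator emulates a birth-cohort autoimmunity study: children enter
between birth and age 8 (a mix of newborns and later enrollees), attend
scheduled clinic visits at 9, 15 and 24 months and annually thereafter, and
an event is recorded at the first positive visit.  The latent onset age is
drawn from the hazard

    h(t | x) = h0(t) * exp( sum_j beta_j(t) * (x_j(t) - c_j) )

by piecewise-exponential inversion on a fine age grid, where h0 is a
piecewise-constant baseline, each beta_j(t) is a user-specified constant,
linear or spline log-hazard-ratio curve, and c_j is an optional centering
constant (absorbed into the baseline; it stabilises realized event counts
for covariates with a large mean).  Detection at scheduled visits induces
the observable quantities: the recorded event age is the first attended
visit at or after onset, censoring is the last attended negative visit, and
onsets that precede the first attended visit yield left-censored cases
(positive at first visit), which the analysis pipeline excludes.

Time-varying exposures follow a latent linear-in-age subject trajectory;
the measurement table reports the trajectory (plus measurement noise) at
attended visits only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import exclude_left_censored, expand_counting_process, fit_cox
from .rcs import fit_rcs_cox, hierarchical_tests
from .supremum import supremum_test
from .zph import zph_test

__all__ = [
    "SimulationScenario",
    "named_scenario",
    "simulate_event_time",
    "apply_visit_detection",
    "simulate_cohort",
    "power_study",
    "rejection_rates",
    "hr_sign_recovery",
    "scenario_manifest",
    "records_from_frame",
    "series_from_frame",
    "POWER_TESTS",
]

_DEFAULT_VISITS = (0.75, 1.25, 2.0) + tuple(float(a) for a in range(3, 14))


@dataclass(frozen=True)
class SimulationScenario:
    """Full description of one simulated cohort design.

    ``baseline_ages``/``baseline_rates`` define a piecewise-constant
    per-year baseline hazard (left edges; the last piece extends to
    ``max_follow_up``).  ``beta_spec`` maps covariate names to log-hazard-
    ratio curves: ``("constant", c)``, ``("linear", a, b)`` for a + b*t, or
    ``("spline", knots, values)`` (natural cubic through the points, linear
    tails).  ``covariate_generators`` maps names to distributions:
    ``{"type": "bernoulli", "p": ...}``, ``{"type": "normal", "mu": ...,
    "sigma": ...}`` or ``{"type": "exposure", "mean": ..., "between_sd":
    ..., "slope": ..., "within_sd": ...}`` for a subject-level time series.
    """

    name: str = "custom"
    n_subjects: int = 1000
    baseline_ages: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0, 10.0)
    baseline_rates: tuple[float, ...] = (0.006, 0.012, 0.007, 0.005, 0.008)
    beta_spec: dict = field(default_factory=dict)
    covariate_generators: dict = field(default_factory=dict)
    newborn_fraction: float = 0.55
    max_entry_age: float = 8.0
    visit_schedule: tuple[float, ...] = _DEFAULT_VISITS
    visit_jitter_sd: float = 0.1
    dropout_rate: float = 0.05
    max_follow_up: float = 13.0
    grid_step: float = 0.05
    seed: int = 0
    test_covariate: str = "x"
    adjustment: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.baseline_rates):
            raise ValueError("baseline rates must be >= 0")
        if len(self.baseline_ages) != len(self.baseline_rates):
            raise ValueError("baseline_ages and baseline_rates must align")
        if any(b <= a for a, b in zip(self.visit_schedule, self.visit_schedule[1:])):
            raise ValueError("visit ages must increase")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be >= 0")
        if self.grid_step > 0.05 + 1e-12:
            raise ValueError("grid_step must be <= 0.05 years")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_ages"] = list(self.baseline_ages)
        d["baseline_rates"] = list(self.baseline_rates)
        d["visit_schedule"] = list(self.visit_schedule)
        d["adjustment"] = list(self.adjustment)
        d["beta_spec"] = {
            k: _beta_spec_to_dict(v) for k, v in self.beta_spec.items()
        }
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        d = dict(d)
        d["baseline_ages"] = tuple(d.get("baseline_ages", cls.baseline_ages))
        d["baseline_rates"] = tuple(d.get("baseline_rates", cls.baseline_rates))
        d["visit_schedule"] = tuple(d.get("visit_schedule", _DEFAULT_VISITS))
        d["adjustment"] = tuple(d.get("adjustment", ()))
        d["beta_spec"] = {
            k: _beta_spec_from_dict(v) for k, v in d.get("beta_spec", {}).items()
        }
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationScenario":
        return cls.from_dict(yaml.safe_load(text))


def _beta_spec_to_dict(spec) -> dict:
    kind = spec[0]
    if kind == "constant":
        return {"type": "constant", "value": float(spec[1])}
    if kind == "linear":
        return {"type": "linear", "intercept": float(spec[1]), "slope": float(spec[2])}
    if kind == "spline":
        return {
            "type": "spline",
            "knots": [float(x) for x in spec[1]],
            "values": [float(x) for x in spec[2]],
        }
    raise ValueError(f"unknown beta spec {spec!r}")


def _beta_spec_from_dict(d):
    if isinstance(d, (tuple, list)) and d and d[0] in ("constant", "linear", "spline"):
        return tuple(d)
    kind = d["type"]
    if kind == "constant":
        return ("constant", d["value"])
    if kind == "linear":
        return ("linear", d["intercept"], d["slope"])
    if kind == "spline":
        return ("spline", tuple(d["knots"]), tuple(d["values"]))
    raise ValueError(f"unknown beta spec {d!r}")


def beta_function(spec) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorised beta(t) for a ("constant",c) / ("linear",a,b) /
    ("spline", knots, values) specification."""
    kind = spec[0]
    if kind == "constant":
        c = float(spec[1])
        return lambda t: np.full_like(np.asarray(t, dtype=float), c)
    if kind == "linear":
        a, b = float(spec[1]), float(spec[2])
        return lambda t: a + b * np.asarray(t, dtype=float)
    if kind == "spline":
        from scipy.interpolate import CubicSpline

        knots = np.asarray(spec[1], dtype=float)
        values = np.asarray(spec[2], dtype=float)
        cs = CubicSpline(knots, values, bc_type="natural")
        d0, d1 = cs(knots[0], 1), cs(knots[-1], 1)

        def f(t):
            t = np.asarray(t, dtype=float)
            out = cs(np.clip(t, knots[0], knots[-1]))
            out = np.where(t < knots[0], values[0] + d0 * (t - knots[0]), out)
            out = np.where(t > knots[-1], values[-1] + d1 * (t - knots[-1]), out)
            return out

        return f
    raise ValueError(f"unknown beta spec {spec!r}")


def named_scenario(name: str, n_subjects: int | None = None, seed: int = 0) -> SimulationScenario:
    """Built-in scenario library.

    * ``null`` — one Bernoulli(0.5) covariate with no effect; constant
      baseline.  Calibration test bed (defaults to n=300).
    * ``nhw-like`` — binary covariate (prevalence 0.72) whose log hazard
      ratio declines linearly from positive to negative with age, plus two
      binary adjustment covariates with constant effects.
    * ``maternal-age-like`` — Normal(30, 5.7) covariate with a nonlinear,
      sign-reversing per-unit effect.
    * ``n3fa-like`` — time-varying exposure trajectory with a linearly
      declining effect.

    The shaped scenarios are qualitative emulations of published age-varying
    hazard-ratio patterns for a type 1 diabetes birth cohort; no study
    parameters are claimed.
    """
    adj_gen = {
        "hla": {"type": "bernoulli", "p": 0.20},
        "fdr": {"type": "bernoulli", "p": 0.45},
    }
    adj_beta = {"hla": ("constant", 0.92), "fdr": ("constant", 0.64)}
    if name == "null":
        return SimulationScenario(
            name="null",
            n_subjects=300 if n_subjects is None else n_subjects,
            baseline_ages=(0.0,),
            baseline_rates=(0.02,),
            beta_spec={"x": ("constant", 0.0)},
            covariate_generators={"x": {"type": "bernoulli", "p": 0.5}},
            seed=seed,
            test_covariate="x",
        )
    if name == "nhw-like":
        return SimulationScenario(
            name="nhw-like",
            n_subjects=1000 if n_subjects is None else n_subjects,
            beta_spec={"nhw": ("linear", 0.777, -0.111), **adj_beta},
            covariate_generators={"nhw": {"type": "bernoulli", "p": 0.72}, **adj_gen},
            seed=seed,
            test_covariate="nhw",
            adjustment=("hla", "fdr"),
        )
    if name == "maternal-age-like":
        return SimulationScenario(
            name="maternal-age-like",
            n_subjects=1000 if n_subjects is None else n_subjects,
            beta_spec={
                "maternal_age": (
                    "spline",
                    (0.0, 2.0, 6.0, 11.0),
                    (0.040, 0.0262, 0.0, -0.0373),
                ),
                **adj_beta,
            },
            covariate_generators={
                "maternal_age": {"type": "normal", "mu": 30.0, "sigma": 5.7, "center": 30.0},
                **adj_gen,
            },
            seed=seed,
            test_covariate="maternal_age",
            adjustment=("hla", "fdr"),
        )
    if name == "n3fa-like":
        return SimulationScenario(
            name="n3fa-like",
            n_subjects=1000 if n_subjects is None else n_subjects,
            beta_spec={"n3fa": ("linear", 0.36, -0.142), **adj_beta},
            covariate_generators={
                "n3fa": {
                    "type": "exposure",
                    "mean": 1.15,
                    "between_sd": 0.35,
                    "slope": 0.01,
                    "within_sd": 0.10,
                    "center": 1.15,
                },
                **adj_gen,
            },
            seed=seed,
            test_covariate="n3fa",
            adjustment=("hla", "fdr"),
        )
    raise KeyError(f"unknown scenario {name!r}")


# ---------------------------------------------------------------------------
# Event-time generation
# ---------------------------------------------------------------------------


def _baseline_on_grid(scenario: SimulationScenario, grid: np.ndarray) -> np.ndarray:
    edges = np.asarray(scenario.baseline_ages)
    rates = np.asarray(scenario.baseline_rates)
    idx = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, rates.size - 1)
    return rates[idx]


def simulate_event_time(
    covariate_paths: dict,
    scenario: SimulationScenario,
    rng: np.random.Generator,
    entry_age: float = 0.0,
) -> float | None:
    """Draw one latent onset age by piecewise-exponential inversion.

    ``covariate_paths`` maps covariate names to either a scalar (fixed
    covariate) or a callable ``t -> value`` (time-varying path).  Returns
    the onset age, or ``None`` if the subject survives ``max_follow_up``.
    """
    step = scenario.grid_step
    grid = np.arange(entry_age, scenario.max_follow_up + step, step)
    left = grid[:-1]
    lam = _baseline_on_grid(scenario, left).copy()
    eta = np.zeros_like(left)
    for name, spec in scenario.beta_spec.items():
        bf = beta_function(spec)
        path = covariate_paths[name]
        x = path(left) if callable(path) else float(path)
        center = scenario.covariate_generators.get(name, {}).get("center", 0.0)
        eta = eta + bf(left) * (np.asarray(x, dtype=float) - center)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite log hazard ratio on grid")
    lam = lam * np.exp(eta)
    widths = np.diff(grid)
    cum = np.cumsum(lam * widths)
    target = rng.exponential()
    if target > cum[-1]:
        return None
    c = int(np.searchsorted(cum, target))
    before = cum[c - 1] if c > 0 else 0.0
    return float(grid[c] + (target - before) / lam[c])


def apply_visit_detection(
    true_onset: float | None,
    entry_age: float,
    visit_schedule: Sequence[float],
    dropout_age: float,
    max_follow_up: float,
) -> dict | None:
    """Convert a latent onset age into observed cohort-record fields.

    Attended visits are the scheduled ages after entry (plus an enrolment
    visit for subjects entering after birth), truncated at dropout and
    administrative end of follow-up.  Returns ``None`` for subjects with no
    usable follow-up (no attended visit after entry).
    """
    obs_end = min(dropout_age, max_follow_up)
    if entry_age > 0:
        attended = [entry_age] + [v for v in visit_schedule if v > entry_age]
    else:
        attended = list(visit_schedule)
    attended = [v for v in attended if v <= obs_end]
    if not attended:
        return None
    if true_onset is not None and true_onset <= attended[-1]:
        detect = next(v for v in attended if v >= true_onset)
        if detect <= entry_age:
            return None
        return {
            "entry_age": entry_age,
            "exit_age": detect,
            "event": True,
            "positive_at_first_visit": detect == attended[0] and entry_age == 0.0,
        }
    exit_age = attended[-1]
    if exit_age <= entry_age:
        return None
    return {
        "entry_age": entry_age,
        "exit_age": exit_age,
        "event": False,
        "positive_at_first_visit": False,
    }


def simulate_cohort(
    scenario: SimulationScenario,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Simulate a full cohort: subject table and optional measurement table.

    Fully reproducible from ``scenario.seed``.  The measurement table is
    returned only when the scenario contains an exposure-type (time-varying)
    covariate; it reports values at attended visits up to each subject's
    exit age.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_subjects
    cols: dict[str, np.ndarray] = {}
    exposure_name = None
    exposure_base = exposure_slope = exposure_within = None
    for name, gen in scenario.covariate_generators.items():
        kind = gen["type"]
        if kind == "bernoulli":
            cols[name] = rng.binomial(1, gen["p"], size=n).astype(float)
        elif kind == "normal":
            cols[name] = rng.normal(gen["mu"], gen["sigma"], size=n)
        elif kind == "exposure":
            if exposure_name is not None:
                raise ValueError("at most one exposure-type covariate supported")
            exposure_name = name
            exposure_base = rng.normal(gen["mean"], gen["between_sd"], size=n)
            exposure_slope = float(gen.get("slope", 0.0))
            exposure_within = float(gen.get("within_sd", 0.0))
        else:
            raise ValueError(f"unknown covariate generator {kind!r}")

    is_newborn = rng.random(n) < scenario.newborn_fraction
    entries = np.where(
        is_newborn, 0.0, rng.uniform(0.0, scenario.max_entry_age, size=n)
    )
    dropout = entries + (
        rng.exponential(1.0 / scenario.dropout_rate, size=n)
        if scenario.dropout_rate > 0
        else np.full(n, np.inf)
    )

    rows = []
    meas_rows = []
    sched = np.asarray(scenario.visit_schedule)
    for i in range(n):
        paths: dict = {name: cols[name][i] for name in cols}
        if exposure_name is not None:
            b, s = float(exposure_base[i]), exposure_slope
            paths[exposure_name] = lambda t, b=b, s=s: b + s * np.asarray(t, dtype=float)
        # each child attends around the scheduled ages, not exactly on them
        if scenario.visit_jitter_sd > 0:
            visits = np.sort(
                np.clip(
                    sched + rng.normal(0.0, scenario.visit_jitter_sd, sched.size),
                    0.05,
                    None,
                )
            )
        else:
            visits = sched
        onset = simulate_event_time(paths, scenario, rng, entry_age=float(entries[i]))
        rec = apply_visit_detection(
            onset, float(entries[i]), tuple(visits), float(dropout[i]),
            scenario.max_follow_up,
        )
        if rec is None:
            continue
        sid = f"S{i:06d}"
        row = {"subject_id": sid, **rec}
        for name in cols:
            row[name] = cols[name][i]
        rows.append(row)
        if exposure_name is not None:
            if rec["entry_age"] > 0:
                attended = [rec["entry_age"]] + [
                    float(v) for v in visits if v > rec["entry_age"]
                ]
            else:
                attended = [float(v) for v in visits]
            for v in attended:
                if v > rec["exit_age"]:
                    break
                noise = rng.normal(0.0, exposure_within) if exposure_within > 0 else 0.0
                meas_rows.append(
                    {
                        "subject_id": sid,
                        "age": v,
                        "value": float(exposure_base[i]) + exposure_slope * v + noise,
                    }
                )

    subjects = pd.DataFrame(rows)
    if not rows:
        subjects = pd.DataFrame(
            columns=["subject_id", "entry_age", "exit_age", "event",
                     "positive_at_first_visit", *cols]
        )
    subjects["event"] = subjects.get("event", pd.Series(dtype=bool)).astype(int)
    subjects["positive_at_first_visit"] = subjects.get(
        "positive_at_first_visit", pd.Series(dtype=bool)
    ).astype(int)
    measurements = pd.DataFrame(meas_rows) if exposure_name is not None else None
    if subjects["event"].sum() == 0:
        import warnings

        warnings.warn("simulated cohort has zero events; downstream fits will fail")
    return subjects, measurements


def scenario_manifest(
    scenario: SimulationScenario, subjects: pd.DataFrame
) -> dict:
    """Reproducibility manifest: scenario hash, seed and realized counts."""
    digest = hashlib.sha256(scenario.to_yaml().encode()).hexdigest()
    return {
        "scenario": scenario.name,
        "scenario_sha256": digest,
        "seed": scenario.seed,
        "n_subjects": int(len(subjects)),
        "n_events": int(subjects["event"].sum()) if len(subjects) else 0,
        "n_left_censored": int(subjects["positive_at_first_visit"].sum())
        if len(subjects)
        else 0,
    }


# ---------------------------------------------------------------------------
# Cohort table <-> record conversion
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "subject_id",
    "entry_age",
    "exit_age",
    "event",
    "positive_at_first_visit",
)


def records_from_frame(df: pd.DataFrame):
    """Convert a subject table to :class:`~coxdiag.core.CohortRecord` list."""
    from .core import CohortRecord

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing required columns: {missing}")
    cov_names = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        d = row._asdict()
        for c in REQUIRED_COLUMNS + tuple(cov_names):
            if pd.isna(d[c]):
                raise ValueError(f"line {i}: missing value in column {c!r}")
        records.append(
            CohortRecord(
                subject_id=str(d["subject_id"]),
                entry_age=float(d["entry_age"]),
                exit_age=float(d["exit_age"]),
                event=bool(int(d["event"])),
                positive_at_first_visit=bool(int(d["positive_at_first_visit"])),
                covariates={c: float(d[c]) for c in cov_names},
            )
        )
    return records


def series_from_frame(df: pd.DataFrame):
    """Convert a long measurement table to per-subject measurement series."""
    from .core import MeasurementSeries

    for c in ("subject_id", "age", "value"):
        if c not in df.columns:
            raise ValueError(f"measurement table missing column {c!r}")
    out = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("age")
        out[str(sid)] = MeasurementSeries(
            subject_id=str(sid),
            observations=tuple(
                (float(a), float(v)) for a, v in zip(grp["age"], grp["value"])
            ),
        )
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo rejection-rate studies
# ---------------------------------------------------------------------------

POWER_TESTS = (
    "supremum",
    "zph_global",
    "zph_individual",
    "rcs_association",
    "rcs_nonconstant",
    "rcs_nonlinear",
)


def _one_rep_pvalues(
    scenario: SimulationScenario, tests: Sequence[str], rep_seed: int
) -> dict[str, float]:
    """Simulate one cohort and compute the requested diagnostics' p-values."""
    sc = replace(scenario, seed=int(rep_seed))
    subjects, measurements = simulate_cohort(sc)
    records = records_from_frame(subjects)
    records, _ = exclude_left_censored(records)
    cov = sc.test_covariate
    tv = measurements is not None and cov not in subjects.columns
    if tv:
        ids = {r.subject_id for r in records}
        series = {
            k: v for k, v in series_from_frame(measurements).items() if k in ids
        }
        episodes = expand_counting_process(records, series, covariate_name=cov)
    else:
        episodes = expand_counting_process(records)

    out: dict[str, float] = {}
    names = list(sc.adjustment) + [cov]
    need_plain = any(t in tests for t in ("supremum", "zph_global", "zph_individual"))
    if need_plain:
        fit = fit_cox(episodes, names)
        if "supremum" in tests:
            # decorrelate the multiplier stream from the cohort stream:
            # reusing rep_seed would replay the very uniforms that generated
            # the data and bias the resampled null paths
            resample_seed = int((rep_seed * 2654435761 + 97) % (2**31 - 1))
            out["supremum"] = supremum_test(
                fit, cov, n_paths=1000, seed=resample_seed
            ).p_value
        if "zph_global" in tests or "zph_individual" in tests:
            z = zph_test(fit, with_curves=False)
            out["zph_global"] = z.global_p
            out["zph_individual"] = float(
                z.p_values[z.covariate_names.index(cov)]
            )
    if any(t.startswith("rcs") for t in tests):
        rf = fit_rcs_cox(episodes, cov, adjustment=sc.adjustment, knots_k=3)
        ht = hierarchical_tests(rf, gate=False)
        out["rcs_association"] = ht.association[2]
        out["rcs_nonconstant"] = ht.nonconstant[2]
        out["rcs_nonlinear"] = (
            ht.nonlinear[2] if ht.nonlinear is not None else float("nan")
        )
    return out


def rejection_rates(
    scenario: SimulationScenario,
    tests: Sequence[str],
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection proportions of several diagnostics over shared replicates.

    Simulates ``n_reps`` cohorts and runs every requested test on each, so
    calibration studies of multiple diagnostics reuse one set of cohorts.
    Returns per-test rejection proportions with Wilson 95% intervals.
    """
    bad = [t for t in tests if t not in POWER_TESTS]
    if bad:
        raise ValueError(f"unknown tests {bad}; choose from {POWER_TESTS}")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    counts = {t: 0 for t in tests}
    n_ok = {t: 0 for t in tests}
    n_failed = 0
    for s in rep_seeds:
        try:
            p = _one_rep_pvalues(scenario, tuple(tests), int(s))
        except Exception:
            n_failed += 1
            continue
        for t in tests:
            if np.isfinite(p[t]):
                n_ok[t] += 1
                counts[t] += p[t] < alpha
    out = {"n_reps": n_reps, "n_failed": n_failed, "alpha": alpha, "seed": seed,
           "scenario": scenario.name, "tests": {}}
    for t in tests:
        prop = counts[t] / n_ok[t] if n_ok[t] else float("nan")
        lo, hi = _wilson_interval(counts[t], n_ok[t])
        out["tests"][t] = {
            "rejection_proportion": prop,
            "n_used": n_ok[t],
            "ci95": [lo, hi],
        }
    return out


def power_study(
    scenario: SimulationScenario,
    test_name: str,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Monte-Carlo rejection proportion of one diagnostic under a scenario.

    Replicate seeds are drawn from a generator seeded with ``seed``; cohort
    replicates that fail to fit (e.g. zero events) are excluded and counted.
    Returns the rejection proportion with a Wilson 95% interval.
    """
    if test_name not in POWER_TESTS:
        raise ValueError(f"unknown test {test_name!r}; choose from {POWER_TESTS}")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    rejections = 0
    n_ok = 0
    n_failed = 0
    for s in rep_seeds:
        try:
            p = _one_rep_pvalues(scenario, (test_name,), int(s))[test_name]
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(p):
            n_failed += 1
            continue
        n_ok += 1
        rejections += p < alpha
    prop = rejections / n_ok if n_ok else float("nan")
    lo, hi = _wilson_interval(rejections, n_ok)
    return {
        "test": test_name,
        "scenario": scenario.name,
        "n_reps": n_reps,
        "n_failed": n_failed,
        "alpha": alpha,
        "seed": seed,
        "rejection_proportion": prop,
        "ci95": [lo, hi],
    }


def hr_sign_recovery(
    scenario: SimulationScenario,
    n_reps: int,
    seed: int = 0,
    early_age: float = 2.0,
    late_age: float = 11.0,
) -> dict:
    """How often the fitted spline HR(t) recovers a sign-reversing pattern.

    For each replicate cohort, fits the 3-knot time-interaction model for
    the scenario's test covariate and records whether the fitted hazard
    ratio exceeds 1 at ``early_age`` and falls below 1 at ``late_age``.
    """
    from .rcs import hr_curve

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    hits = 0
    n_ok = 0
    n_failed = 0
    for s in rep_seeds:
        sc = replace(scenario, seed=int(s))
        subjects, measurements = simulate_cohort(sc)
        records = records_from_frame(subjects)
        records, _ = exclude_left_censored(records)
        try:
            if measurements is not None:
                ids = {r.subject_id for r in records}
                series = {
                    k: v
                    for k, v in series_from_frame(measurements).items()
                    if k in ids
                }
                episodes = expand_counting_process(
                    records, series, covariate_name=sc.test_covariate
                )
            else:
                episodes = expand_counting_process(records)
            rf = fit_rcs_cox(
                episodes, sc.test_covariate, adjustment=sc.adjustment, knots_k=3
            )
            curve = hr_curve(rf, [early_age, late_age])
        except Exception:
            n_failed += 1
            continue
        n_ok += 1
        hits += (curve[0, 1] > 1.0) and (curve[1, 1] < 1.0)
    prop = hits / n_ok if n_ok else float("nan")
    lo, hi = _wilson_interval(hits, n_ok)
    return {
        "scenario": scenario.name,
        "n_reps": n_reps,
        "n_used": n_ok,
        "n_failed": n_failed,
        "early_age": early_age,
        "late_age": late_age,
        "recovery_proportion": prop,
        "ci95": [lo, hi],
        "seed": seed,
    }


def _wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return float("nan"), float("nan")
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)
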