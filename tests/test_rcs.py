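"""Spline basis, time-interaction fits, hierarchical tests and HR curves."""

import numpy as np
import pytest
from scipy import stats

from coxdiag.core import (
    CohortRecord,
    Episode,
    MeasurementSeries,
    expand_counting_process,
    fit_cox,
)
from coxdiag.rcs import (
    HierarchicalTests,
    RcsBasis,
    RcsFit,
    fit_rcs_cox,
    hierarchical_tests,
    hr_curve,
    null_loglik,
    place_knots,
    rcs_basis_eval,
    select_knots_by_aic,
)

from conftest import frame_to_episodes, random_survival_frame


def survival_episodes(seed=31, n=250, scale=9.0):
    rng = np.random.default_rng(seed)
    T = rng.exponential(scale, n)
    C = rng.uniform(2, 13, n)
    t = np.minimum(T, C)
    e = T <= C
    x = rng.binomial(1, 0.5, n).astype(float)
    return [
        Episode(f"s{i}", 0.0, float(t[i]), {"x": float(x[i])}, bool(e[i]))
        for i in range(n)
    ]


class TestPlaceKnots:
    def test_default_percentiles_against_order_statistic_oracle(self):
        ages = np.arange(1.0, 21.0)  # 1..20
        basis = place_knots(ages)

        def quantile(sorted_x, q):
            # explicit linear interpolation between order statistics
            h = (len(sorted_x) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_x) - 1)
            return sorted_x[lo] + (h - lo) * (sorted_x[hi] - sorted_x[lo])

        expected = tuple(quantile(sorted(ages), q) for q in (0.05, 0.50, 0.95))
        assert basis.knots == pytest.approx(expected)

    def test_degenerate_ages_error(self):
        with pytest.raises(ValueError):
            place_knots([3.0, 3.0, 3.0, 3.0])

    def test_requires_k_distinct_ages(self):
        with pytest.raises(ValueError):
            place_knots([1.0, 2.0], k=3)

    def test_knots_strictly_increase(self):
        basis = place_knots(np.linspace(0.5, 12, 57), k=4)
        assert all(b > a for a, b in zip(basis.knots, basis.knots[1:]))


class TestBasis:
    BASIS = RcsBasis((2.0, 6.0, 10.0))

    def test_before_first_knot_nonlinear_terms_vanish(self):
        v = rcs_basis_eval(1.5, self.BASIS)
        assert v[0] == 1.5
        assert v[1] == 0.0

    def test_closed_form_truncated_power_values(self):
        # tau = (10-2)^2 = 64; at t=6: (6-2)^3/64 = 1;  at t=8:
        # ((8-2)^3 - (8-6)^3 * (10-2)/(10-6)) / 64 = (216 - 16)/64 = 3.125
        assert rcs_basis_eval(6.0, self.BASIS)[1] == pytest.approx(1.0)
        assert rcs_basis_eval(8.0, self.BASIS)[1] == pytest.approx(3.125)

    def test_linear_in_the_tail(self):
        t = np.linspace(10.5, 20.0, 25)
        vals = rcs_basis_eval(t, self.BASIS)[:, 1]
        third_diff = np.diff(vals, n=3)
        np.testing.assert_allclose(third_diff, 0.0, atol=1e-9)
        second_diff = np.diff(vals, n=2)
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)

    @pytest.mark.parametrize("knot", [2.0, 6.0, 10.0])
    def test_c2_continuity_at_knots(self, knot):
        h = 1e-5
        f = lambda t: rcs_basis_eval(t, self.BASIS)[1]
        for deriv in range(3):
            if deriv == 0:
                left, right = f(knot - 1e-9), f(knot + 1e-9)
            else:
                left = (f(knot - h + h / 2) - f(knot - h - h / 2)) / h
                right = (f(knot + h + h / 2) - f(knot + h - h / 2)) / h
                if deriv == 2:
                    left = (f(knot - 2 * h) - 2 * f(knot - h) + f(knot)) / h**2
                    right = (f(knot) - 2 * f(knot + h) + f(knot + 2 * h)) / h**2
            assert left == pytest.approx(right, abs=1e-3)

    def test_non_finite_t_errors(self):
        with pytest.raises(ValueError):
            rcs_basis_eval(np.nan, self.BASIS)

    def test_fewer_than_three_knots_rejected(self):
        with pytest.raises(ValueError):
            RcsBasis((1.0, 2.0))


class TestFitRcsCox:
    def test_constant_only_refit_reproduces_standard_cox(self):
        eps = survival_episodes()
        rf = fit_rcs_cox(eps, "x", knots_k=3)
        reduced = rf._refit(1)
        plain = fit_cox(eps, ["x"])
        assert reduced.coefficients[0] == pytest.approx(
            plain.coefficients[0], abs=1e-10
        )
        assert reduced.loglik == pytest.approx(plain.loglik, abs=1e-10)

    def test_nesting_loglik_ordering(self):
        eps = survival_episodes()
        rf = fit_rcs_cox(eps, "x", knots_k=3)
        ll_null = null_loglik(eps)
        ll_const = rf._nested_loglik(1)
        ll_lin = rf._nested_loglik(2)
        assert ll_null <= ll_const + 1e-9
        assert ll_const <= ll_lin + 1e-9
        assert ll_lin <= rf.loglik + 1e-9

    def test_delta_scales_curve_not_fit(self):
        eps = survival_episodes()
        r1 = fit_rcs_cox(eps, "x", delta=1.0)
        r5 = fit_rcs_cox(eps, "x", delta=5.0)
        np.testing.assert_allclose(r1.fit.coefficients, r5.fit.coefficients)
        grid = [2.0, 5.0, 9.0]
        c1 = hr_curve(r1, grid)
        c5 = hr_curve(r5, grid)
        np.testing.assert_allclose(c5[:, 1], c1[:, 1] ** 5, rtol=1e-10)

    def test_aic_definition(self):
        eps = survival_episodes()
        rf = fit_rcs_cox(eps, "x", knots_k=3)
        assert rf.aic == pytest.approx(-2 * rf.loglik + 2 * 3)

    def test_knots_outside_followup_rejected(self):
        eps = survival_episodes()
        with pytest.raises(ValueError, match="outside the follow-up|outside follow-up"):
            fit_rcs_cox(eps, "x", basis=RcsBasis((1.0, 8.0, 99.0)))

    def test_time_varying_constant_series_equals_fixed_path(self):
        """A per-subject-constant measurement series must reproduce the
        fixed-covariate fit exactly."""
        rng = np.random.default_rng(77)
        records, series = [], {}
        for i in range(150):
            t_exit = float(rng.uniform(1.0, 12.0))
            event = bool(rng.random() < 0.5)
            x = float(rng.normal(0, 1))
            records.append(
                CohortRecord(f"s{i}", 0.0, t_exit, event, covariates={"x": x})
            )
            ages = [0.4] + [a for a in (2.0, 5.0, 8.0) if a < t_exit]
            series[f"s{i}"] = MeasurementSeries(
                f"s{i}", tuple((a, x) for a in ages)
            )
        fixed_eps = [
            Episode(r.subject_id, 0.4, r.exit_age, dict(r.covariates), r.event)
            for r in records
            if r.exit_age > 0.4
        ]
        tv_records = [r for r in records if r.exit_age > 0.4]
        tv_eps = expand_counting_process(
            tv_records, {k: v for k, v in series.items()
                         if any(r.subject_id == k for r in tv_records)},
            covariate_name="x",
        )
        f_fixed = fit_rcs_cox(fixed_eps, "x", knots_k=3)
        f_tv = fit_rcs_cox(tv_eps, "x", basis=f_fixed.basis)
        np.testing.assert_allclose(
            f_fixed.fit.coefficients, f_tv.fit.coefficients, atol=1e-8
        )
        assert f_fixed.loglik == pytest.approx(f_tv.loglik, abs=1e-8)


def _dummy_rcsfit(theta, cov, knots=(1.0, 5.0, 11.0)):
    from coxdiag.core import CoxFit

    theta = np.asarray(theta, dtype=float)
    fit = CoxFit(
        covariate_names=tuple(f"t{i}" for i in range(theta.size)),
        coefficients=theta,
        covariance=np.asarray(cov, dtype=float),
        loglik=0.0,
        ties="breslow",
        converged=True,
        n_subjects=10,
        n_events=5,
        event_times=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        event_subject_ids=list("abcde"),
        schoenfeld=np.zeros((5, theta.size)),
        event_info=np.zeros((5, theta.size, theta.size)),
        distinct_times=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        n_at_risk=np.array([5, 4, 3, 2, 1]),
        n_events_at=np.array([1, 1, 1, 1, 1]),
        baseline_increments=np.zeros(5),
        martingale={},
        score_at_solution=np.zeros(theta.size),
        time_varying=False,
    )
    return RcsFit(
        covariate="x",
        adjustment=(),
        basis=RcsBasis(knots),
        delta=1.0,
        fit=fit,
        theta_index=np.arange(theta.size),
        time_varying_extension=False,
    )


class TestHierarchicalTests:
    def test_df_structure_for_three_knots(self):
        eps = survival_episodes()
        rf = fit_rcs_cox(eps, "x", knots_k=3)
        ht = hierarchical_tests(rf, gate=False)
        assert ht.association[1] == 3
        assert ht.nonconstant[1] == 2
        assert ht.nonlinear[1] == 1

    def test_df_structure_for_four_knots(self):
        eps = survival_episodes(seed=5, n=400)
        rf = fit_rcs_cox(eps, "x", knots_k=4)
        ht = hierarchical_tests(rf, gate=False, method="wald")
        assert (ht.association[1], ht.nonconstant[1], ht.nonlinear[1]) == (4, 3, 2)

    def test_gating_blocks_later_tests(self):
        rf = _dummy_rcsfit([1e-8, 1e-8, 1e-8], np.eye(3))
        ht = hierarchical_tests(rf, method="wald")
        assert ht.association[2] > 0.99
        assert ht.nonconstant is None
        assert ht.nonlinear is None
        assert ht.to_dict()["nonconstant"]["na_reason"] == "gated"

    def test_wald_statistic_matches_matrix_oracle(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(3, 3))
        V = A @ A.T + 3 * np.eye(3)
        theta = rng.normal(size=3)
        rf = _dummy_rcsfit(theta, V)
        ht = hierarchical_tests(rf, gate=False, method="wald")
        expected = theta @ np.linalg.inv(V) @ theta
        assert ht.association[0] == pytest.approx(expected, rel=1e-10)
        sub = theta[1:] @ np.linalg.inv(V[1:, 1:]) @ theta[1:]
        assert ht.nonconstant[0] == pytest.approx(sub, rel=1e-10)
        assert ht.association[2] == pytest.approx(
            stats.chi2.sf(expected, 3), rel=1e-12
        )

    def test_lr_and_wald_agree_roughly(self):
        eps = survival_episodes(seed=8, n=400, scale=6.0)
        rf = fit_rcs_cox(eps, "x", knots_k=3)
        w = hierarchical_tests(rf, gate=False, method="wald")
        l = hierarchical_tests(rf, gate=False, method="lr")
        assert w.nonconstant[0] == pytest.approx(l.nonconstant[0], rel=0.5)
        assert l.nonconstant[0] >= 0.0


class TestSelectKnots:
    def test_single_candidate_returned(self):
        eps = survival_episodes()
        rf = select_knots_by_aic(eps, "x", candidate_k=(3,))
        assert rf.basis.k == 3

    def test_minimal_aic_selected_with_tie_toward_fewer(self):
        eps = survival_episodes(seed=12, n=350)
        fits = {}
        for k in (3, 4, 5):
            try:
                fits[k] = fit_rcs_cox(eps, "x", knots_k=k)
            except Exception:
                continue  # a failing candidate must simply be skipped
        assert 3 in fits
        best = select_knots_by_aic(eps, "x", candidate_k=(3, 4, 5))
        best_aic = min(f.aic for f in fits.values())
        assert best.aic == pytest.approx(best_aic)
        # any model tying the best AIC must not have fewer knots than chosen
        tied = [k for k, f in fits.items() if abs(f.aic - best_aic) < 1e-12]
        assert best.basis.k == min(tied)

    def test_all_candidates_failing_propagates(self):
        eps = survival_episodes()[:6]
        with pytest.raises(Exception):
            select_knots_by_aic(eps, "x", candidate_k=(9,))


class TestHrCurve:
    def test_constant_theta_gives_flat_curve(self):
        V = np.diag([0.04, 1e-12, 1e-12])
        rf = _dummy_rcsfit([0.5, 0.0, 0.0], V)
        curve = hr_curve(rf, [1.5, 3.0, 4.5])
        np.testing.assert_allclose(curve[:, 1], np.exp(0.5), rtol=1e-9)
        width = curve[:, 3] / curve[:, 2]
        np.testing.assert_allclose(width, width[0], rtol=1e-6)

    def test_delta_method_se_matches_monte_carlo(self):
        eps = survival_episodes(seed=41, n=300, scale=7.0)
        rf = fit_rcs_cox(eps, "x", knots_k=3)
        rng = np.random.default_rng(1)
        draws = rng.multivariate_normal(
            rf.theta, rf.theta_covariance, size=100_000
        )
        for age in (2.0, 6.0, 10.0):
            c = rf.time_basis(age)
            mc_se = np.std(draws @ c)
            assert rf.beta_t_se(age) == pytest.approx(mc_se, rel=0.02)

    def test_hr_is_one_where_beta_crosses_zero(self):
        from scipy.optimize import brentq

        eps = survival_episodes(seed=55, n=300, scale=5.0)
        rf = fit_rcs_cox(eps, "x", knots_k=3)
        lo, hi = rf.fit.event_times.min(), rf.fit.event_times.max()
        f = lambda t: float(rf.beta_t(t))
        grid = np.linspace(lo, hi, 50)
        signs = np.sign([f(t) for t in grid])
        idx = np.nonzero(np.diff(signs))[0]
        if idx.size == 0:
            pytest.skip("no sign change in this realisation")
        root = brentq(f, grid[idx[0]], grid[idx[0] + 1])
        assert hr_curve(rf, [root])[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_extrapolation_flagged_and_warns(self):
        eps = survival_episodes(seed=3)
        rf = fit_rcs_cox(eps, "x", knots_k=3)
        with pytest.warns(UserWarning, match="extrapolation"):
            curve = hr_curve(rf, [13.5, 5.0])
        assert curve[0, 4] == 1.0 and curve[1, 4] == 0.0

    def test_constant_effect_curve_covers_truth(self):
        """Under a constant log hazard ratio the fitted beta(t) +/- 2 SE
        band should cover the true constant at interior grid ages in the
        large majority of replicates."""
        rng = np.random.default_rng(606)
        beta_true = 0.5
        covered = np.zeros(3)
        n_reps = 40
        for _ in range(n_reps):
            n = 400
            x = rng.binomial(1, 0.5, n).astype(float)
            T = rng.exponential(10.0, n) * np.exp(-beta_true * x)
            C = rng.uniform(2, 13, n)
            t = np.minimum(T, C)
            e = T <= C
            eps = [
                Episode(f"s{i}", 0.0, float(t[i]), {"x": float(x[i])}, bool(e[i]))
                for i in range(n)
            ]
            rf = fit_rcs_cox(eps, "x", knots_k=3)
            for j, age in enumerate((2.0, 5.0, 8.0)):
                est = float(rf.beta_t(age))
                se = float(rf.beta_t_se(age))
                covered[j] += abs(est - beta_true) <= 2 * se
        assert np.all(covered / n_reps >= 0.8), covered / n_reps

    def test_directional_recovery_under_sign_reversing_effect(self):
        """Under a declining log hazard ratio the fitted curve should sit
        higher at early ages than at late ages in most replicates."""
        from coxdiag.simulate import (
            named_scenario,
            records_from_frame,
            simulate_cohort,
        )
        from coxdiag.core import exclude_left_censored
        from dataclasses import replace

        sc0 = named_scenario("nhw-like", n_subjects=800)
        hits = 0
        n_reps = 30
        for r in range(n_reps):
            sc = replace(sc0, seed=4000 + r)
            subj, _ = simulate_cohort(sc)
            recs, _ = exclude_left_censored(records_from_frame(subj))
            eps = expand_counting_process(recs)
            rf = fit_rcs_cox(eps, "nhw", adjustment=("hla", "fdr"), knots_k=3)
            hits += float(rf.beta_t(2.0)) > float(rf.beta_t(11.0))
        assert hits / n_reps >= 0.8

    def test_basis_scale_invariance_of_tests_and_curve(self):
        """Any fixed positive rescaling of the curved basis term is a
        reparameterisation: tests and the fitted HR curve are unchanged."""
        eps = survival_episodes(seed=21, n=300)
        rf = fit_rcs_cox(eps, "x", knots_k=3)
        rescaled = RcsBasis(rf.basis.knots, scale_override=1.0)
        rf2 = fit_rcs_cox(eps, "x", basis=rescaled)
        ht1 = hierarchical_tests(rf, gate=False, method="wald")
        ht2 = hierarchical_tests(rf2, gate=False, method="wald")
        assert ht1.association[0] == pytest.approx(ht2.association[0], rel=1e-6)
        assert ht1.nonconstant[0] == pytest.approx(ht2.nonconstant[0], rel=1e-6)
        assert ht1.nonlinear[0] == pytest.approx(ht2.nonlinear[0], rel=1e-6)
        grid = [2.0, 6.0, 10.0]
        np.testing.assert_allclose(
            hr_curve(rf, grid)[:, 1], hr_curve(rf2, grid)[:, 1], rtol=1e-6
        )
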