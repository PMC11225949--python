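import numpy as np
import pytest

from cwitnorms import (
    CenteringConstants,
    FULL_MODEL_TERMS,
    NormativeEquation,
    Subtest,
    design_row,
    diagnostics,
    extract_equation,
    fit_ols,
    select_model,
)
from cwitnorms.cohort_io import ParticipantRecord, Sex
from cwitnorms.normative_regression import (
    CollinearityError,
    design_matrix,
    term_kind,
)
from cwitnorms.normative_regression import test_equality as equality_ztest
from cwitnorms.norm_scoring import norwegian_norms
from cwitnorms.synthetic_cohort import SimulationSpec, simulate_cohort

CENTER = CenteringConstants(age_mean=46.2, edu_mean=15.5)


def _record(age, edu, sex):
    return ParticipantRecord(id="X", age=age, education=edu, sex=sex)


class TestDesignRow:
    def test_centering_means_zero_all_terms(self):
        # education mean 15.5 is not an integer; centre on an integer grid
        center = CenteringConstants(age_mean=46.2, edu_mean=15.0)
        row = design_row(_record(46.2, 15, Sex.MALE), FULL_MODEL_TERMS, center)
        assert np.allclose(row, 0.0)

    def test_age_terms_for_seventy_year_old(self):
        row = design_row(_record(70, 17, Sex.MALE), ("age", "age2"), CENTER)
        assert row[0] == pytest.approx(23.8)
        assert row[1] == pytest.approx(566.44)

    def test_interaction_is_product_of_centered_components(self):
        row = design_row(_record(50, 17, Sex.FEMALE), ("age_x_female",), CENTER)
        assert row[0] == pytest.approx(3.8)
        row_male = design_row(_record(50, 17, Sex.MALE), ("age_x_female",), CENTER)
        assert row_male[0] == 0.0


class TestFitOLS:
    def test_exact_linear_fit_has_zero_residual_sd(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x])
        y = 2.0 + 3.0 * x
        f = fit_ols(X, y, ("age",))
        assert f.sd_residual == pytest.approx(0.0, abs=1e-10)
        assert f.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        """Brute-force (X'X)^-1 X'y with classical standard errors."""
        for _ in range(5):
            n, p = 40, 4
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            f = fit_ols(X, y, ("age", "edu", "female"))
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            sigma2 = resid @ resid / (n - p)
            se = np.sqrt(np.diag(sigma2 * XtX_inv))
            assert np.allclose(f.params, beta, atol=1e-8)
            assert np.allclose(f.bse, se, atol=1e-8)
            assert f.sd_residual == pytest.approx(np.sqrt(sigma2))

    def test_partial_r2_is_t2_over_t2_plus_df(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 0.5, 0.0] + rng.normal(size=n)
        f = fit_ols(X, y, ("age", "edu"))
        for i in range(1, 3):
            t = f.tvalues[i]
            assert f.partial_r2[i] == pytest.approx(t**2 / (t**2 + f.df_resid))

    def test_printed_t_and_df_reconstruct_printed_partial_r2(self):
        # published CWIT-3 age term: t = -15.97 with 1006 residual df -> .202
        t, df = -15.97, 1006
        assert round(t**2 / (t**2 + df), 3) == 0.202
        # and CWIT-4 age: t = -13.83 with 1007 df -> .160
        t, df = -13.83, 1007
        assert round(t**2 / (t**2 + df), 3) == 0.160

    def test_collinearity_names_offending_column(self, rng):
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(CollinearityError, match="edu"):
            fit_ols(X, rng.normal(size=n), ("age", "edu"))


def _simulated_scores(n, seed):
    """Cohort + integer scaled scores per subtest under the published norms."""
    synth = simulate_cohort(SimulationSpec(n=n, seed=seed))
    cohort = synth.cohort
    ns = norwegian_norms()
    scores = {
        st: [ns.tables[st].lookup(r.times[st]) for r in cohort] for st in Subtest
    }
    return cohort, scores


class TestSelectModel:
    def test_recovers_generating_term_structure(self):
        """Simplification lands on the generating terms (age, age2, edu on
        the inhibition/switching condition) and drops the null terms."""
        cohort, scores = _simulated_scores(5000, seed=2024)
        fitted, trace = select_model(
            cohort, scores[Subtest.CWIT4], centering=CENTER
        )
        assert set(fitted.terms) == {"age", "age2", "edu"}
        assert any(s.accepted for s in trace.steps)

    def test_zero_education_effect_drops_education_terms(self, rng):
        n = 3000
        ages = rng.uniform(20, 85, n)
        edus = rng.integers(7, 24, n)
        females = rng.integers(0, 2, n)
        y = 10 - 0.05 * (ages - 46.2) + rng.normal(0, 2.5, n)
        from tests_helpers import cohort_from_arrays

        cohort = cohort_from_arrays(ages, edus, females)
        fitted, _ = select_model(cohort, list(y), centering=CENTER)
        assert not any(t.startswith("edu") for t in fitted.terms)

    def test_marginality_never_violated(self, rng):
        """No selected model contains a power/interaction without its
        lower-order terms, even on pure-noise responses."""
        from tests_helpers import cohort_from_arrays

        deps = {
            "age2": ["age"], "age3": ["age", "age2"],
            "edu2": ["edu"], "edu3": ["edu", "edu2"],
            "age_x_female": ["age", "female"],
            "edu_x_female": ["edu", "female"],
            "age_x_edu": ["age", "edu"],
        }
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 400
            cohort = cohort_from_arrays(
                r.uniform(20, 85, n), r.integers(7, 24, n), r.integers(0, 2, n)
            )
            y = r.normal(10, 3, n)
            fitted, _ = select_model(cohort, list(y), centering=CENTER)
            present = set(fitted.terms)
            for t in present:
                for needed in deps.get(t, []):
                    assert needed in present, (seed, fitted.terms)

    def test_trace_records_bic_each_step(self):
        cohort, scores = _simulated_scores(1000, seed=5)
        _, trace = select_model(cohort, scores[Subtest.CWIT1], centering=CENTER)
        assert trace.steps
        for s in trace.steps:
            assert np.isfinite(s.bic_before) and np.isfinite(s.bic_after)
        assert "drop" in trace.summary()


class TestExtractEquation:
    def test_recovers_generating_intercept_within_two_se(self):
        cohort, scores = _simulated_scores(10_000, seed=77)
        ns = norwegian_norms()
        eq = ns.equations[Subtest.CWIT1]
        terms = list(eq.coefficients)
        ages = [r.age for r in cohort]
        edus = [r.education for r in cohort]
        females = [r.female for r in cohort]
        X = design_matrix(ages, edus, females, terms, CENTER)
        f = fit_ols(X, scores[Subtest.CWIT1], terms)
        assert abs(f.params[0] - 9.863) <= 2 * f.bse[0]

    def test_refit_on_own_predictions_is_exact(self, rng):
        n = 200
        from tests_helpers import cohort_from_arrays

        cohort = cohort_from_arrays(
            rng.uniform(20, 85, n), rng.integers(7, 24, n), rng.integers(0, 2, n)
        )
        terms = ("age", "age2", "female")
        ages = [r.age for r in cohort]
        edus = [r.education for r in cohort]
        females = [r.female for r in cohort]
        X = design_matrix(ages, edus, females, terms, CENTER)
        beta = np.array([10.0, -0.05, -0.001, 0.8])
        y = X @ beta
        f = fit_ols(X, y, terms)
        assert np.allclose(f.params, beta, atol=1e-9)
        assert f.sd_residual == pytest.approx(0.0, abs=1e-9)

    def test_serialized_equation_scores_identically(self, tmp_path):
        cohort, scores = _simulated_scores(1000, seed=3)
        fitted, _ = select_model(cohort, scores[Subtest.CWIT3], centering=CENTER)
        eq = extract_equation(fitted, Subtest.CWIT3, CENTER)
        p = eq.to_json(tmp_path / "eq.json")
        again = NormativeEquation.from_json(p)
        for age, edu, fem in [(25, 10, 0), (60, 18, 1), (84, 23, 1)]:
            assert again.predict(age, edu, fem) == pytest.approx(
                eq.predict(age, edu, fem), abs=1e-12
            )


class TestDiagnostics:
    def test_perfect_fit_has_zero_cooks_distances(self, rng):
        n = 50
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        f = fit_ols(X, 1.0 + 2.0 * x, ("age",))
        d = diagnostics(f)
        assert np.allclose(d.cooks_distance, 0.0, atol=1e-12)

    def test_gross_outlier_has_max_cooks_distance(self, rng):
        n = 40
        x = np.linspace(0, 1, n)
        y = 2 * x + rng.normal(0, 0.05, n)
        y[7] += 5.0  # gross outlier
        X = np.column_stack([np.ones(n), x])
        f = fit_ols(X, y, ("age",))
        d = diagnostics(f)
        assert int(np.argmax(d.cooks_distance)) == 7
        # leave-one-out oracle: deleting row 7 moves the fit most
        full = np.linalg.lstsq(X, y, rcond=None)[0]
        shifts = []
        for i in range(n):
            keep = np.arange(n) != i
            b = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            shifts.append(np.sum((b - full) ** 2))
        assert int(np.argmax(shifts)) == 7

    def test_homoscedastic_simulation_shows_no_trend(self, rng):
        n = 2000
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = 1 + x + rng.normal(0, 1, n)
        d = diagnostics(fit_ols(X, y, ("age",)))
        assert abs(d.abs_resid_vs_fitted_r) < 0.08


class TestEquality:
    def test_same_response_gives_zero_difference(self):
        cohort, scores = _simulated_scores(500, seed=11)
        y = scores[Subtest.CWIT1]
        res = equality_ztest(
            cohort, y, y, ("age", "age2"), ("age", "age2"), "age", centering=CENTER
        )
        assert res.diff == pytest.approx(0.0, abs=1e-10)
        assert res.z == pytest.approx(0.0, abs=1e-8)

    def test_identical_regressors_reduce_sur_to_ols(self):
        """Classical identity: with the same design in both equations the
        FGLS system estimate equals per-equation OLS."""
        cohort, scores = _simulated_scores(800, seed=13)
        terms = ("age", "age2", "female")
        ages = [r.age for r in cohort]
        edus = [r.education for r in cohort]
        females = [r.female for r in cohort]
        X = design_matrix(ages, edus, females, terms, CENTER)
        ya = np.asarray(scores[Subtest.CWIT1], float)
        yb = np.asarray(scores[Subtest.CWIT3], float)
        res = equality_ztest(
            cohort, ya, yb, terms, terms, "age",
            subtest_a=Subtest.CWIT1, subtest_b=Subtest.CWIT3, centering=CENTER,
        )
        ols_a = np.linalg.lstsq(X, ya, rcond=None)[0]
        ols_b = np.linalg.lstsq(X, yb, rcond=None)[0]
        assert res.b1 == pytest.approx(ols_a[1], abs=1e-8)
        assert res.b2 == pytest.approx(ols_b[1], abs=1e-8)

    def test_distinct_age_slopes_rejected(self):
        """Word reading ages far more gently than inhibition; the Z-test
        should detect the difference at alpha = .01."""
        rejected = 0
        for seed in range(5):
            cohort, scores = _simulated_scores(5000, seed=600 + seed)
            res = equality_ztest(
                cohort,
                scores[Subtest.CWIT2],
                scores[Subtest.CWIT3],
                ("age", "age2"),
                ("age", "age2", "edu", "female"),
                "age",
                subtest_a=Subtest.CWIT2,
                subtest_b=Subtest.CWIT3,
                centering=CENTER,
            )
            # reading ages more gently: slope difference is positive
            assert res.diff > 0
            rejected += res.p < 0.01
        assert rejected >= 4

    def test_term_missing_from_model_errors(self):
        cohort, scores = _simulated_scores(200, seed=1)
        with pytest.raises(ValueError, match="both models"):
            equality_ztest(
                cohort, scores[Subtest.CWIT1], scores[Subtest.CWIT2],
                ("age",), ("age", "edu"), "edu", centering=CENTER,
            )
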