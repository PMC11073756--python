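"""Tests for progression tests and the interaction regression."""

import itertools

import numpy as np
import pytest

from uncrflow.features import InflammationSummary
from uncrflow.models import (
    ParticipantOutcome,
    annualized_percent_change,
    cohens_f2,
    fit_inflammation_model,
    one_sample_progression_test,
    paired_progression_test,
    stratified_prediction,
    _tertile_bounds,
)
from uncrflow.simulate import OutcomeParams, generate_cohort


def make_summaries(bg, resp):
    return [
        InflammationSummary(f"p{i}", b, r, 0.0, 0.0, 1)
        for i, (b, r) in enumerate(zip(bg, resp))
    ]


def make_outcomes(y, ids=None, age=None, sex=None):
    return [
        ParticipantOutcome(
            participant_id=ids[i] if ids else f"p{i}",
            cord_atrophy=float(v),
            brain_atrophy=0.0,
            age=float(age[i]) if age is not None else 50.0,
            sex=int(sex[i]) if sex is not None else 0,
            followup_years=2.5,
        )
        for i, v in enumerate(y)
    ]


class TestAnnualizedChange:
    @pytest.mark.parametrize(
        "start, end, years, expected",
        [(100, 98, 2, -1.0), (80, 84, 2.5, 2.0), (55, 55, 7.3, 0.0)],
    )
    def test_arithmetic(self, start, end, years, expected):
        assert annualized_percent_change(start, end, years) == pytest.approx(expected)

    def test_guards(self):
        with pytest.raises(ValueError):
            annualized_percent_change(0, 10, 1)
        with pytest.raises(ValueError):
            annualized_percent_change(10, 10, 0)


class TestOneSampleTest:
    def test_zero_vector_convention(self):
        t, df, p, mean, ci = one_sample_progression_test([0.0] * 10)
        assert (t, p, mean) == (0.0, 1.0, 0.0)
        assert df == 9

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(42)
        x = rng.normal(-2.2, 1.8, size=49)
        t, df, p, mean, ci = one_sample_progression_test(x)
        expected_t = np.mean(x) / (np.std(x, ddof=1) / np.sqrt(49))
        assert t == pytest.approx(expected_t, abs=1e-10)
        assert df == 48
        assert ci[0] < mean < ci[1]

    def test_guards(self):
        with pytest.raises(ValueError):
            one_sample_progression_test([1.0])
        with pytest.raises(ValueError):
            one_sample_progression_test([2.0, 2.0, 2.0])


class TestPairedTest:
    def test_cohens_d_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        base = rng.normal(10, 2, size=50)
        end = base + rng.normal(0.5, 1.0, size=50)
        t, p, d = paired_progression_test(base, end, parametric=True)
        diff = end - base
        assert d == pytest.approx(np.mean(diff) / np.std(diff, ddof=1), abs=1e-12)

    def test_constant_shift_degenerate(self):
        base = np.arange(10.0)
        with pytest.raises(ValueError, match="degenerate"):
            paired_progression_test(base, base + 3.0, parametric=True)

    def test_wilcoxon_against_exact_enumeration(self):
        """Normal-approximation Z agrees with brute-force enumeration of
        all 2^4 sign patterns for diffs (+1, +2, +3, -1)."""
        base = np.zeros(4)
        end = np.array([1.0, 2.0, 3.0, -1.0])
        z, p, eff = paired_progression_test(base, end, parametric=False)
        # signed ranks of |diff| = (1,2,3,1) -> mid-ranks (1.5, 3, 4, 1.5)
        ranks = np.array([1.5, 3.0, 4.0, 1.5])
        signs = np.array([1, 1, 1, -1])
        w_plus = ranks[signs > 0].sum()
        n = 4
        mu = n * (n + 1) / 4
        # tie-corrected variance of W+
        counts = np.array([2, 1, 1])  # tie group sizes of |diffs|
        var = n * (n + 1) * (2 * n + 1) / 24 - (counts**3 - counts).sum() / 48
        expected_z = (w_plus - mu) / np.sqrt(var)
        assert abs(z) == pytest.approx(abs(expected_z), abs=1e-10)
        assert eff == pytest.approx(z / 2.0, abs=1e-12)
        # exact two-sided p from enumerating all sign assignments
        stats = [
            ranks[np.array(sgn) > 0].sum()
            for sgn in itertools.product([-1, 1], repeat=4)
        ]
        exact_p = np.mean([abs(s - mu) >= abs(w_plus - mu) for s in stats])
        # normal approximation should be in the neighbourhood of exact
        assert p == pytest.approx(exact_p, abs=0.25)

    def test_all_zero_diffs_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            paired_progression_test([1.0, 2.0], [1.0, 2.0], parametric=False)


class TestCohensF2:
    @pytest.mark.parametrize(
        "full, red, expected", [(0.5, 0.25, 0.5), (0.3, 0.3, 0.0), (0.12, 0.02, 0.1 / 0.88)]
    )
    def test_formula(self, full, red, expected):
        assert cohens_f2(full, red) == pytest.approx(expected)

    def test_guards(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0, 0.5)
        with pytest.raises(ValueError):
            cohens_f2(0.3, 0.4)


class TestInteractionModel:
    def test_noise_free_recovery_of_generating_coefficients(self):
        op = OutcomeParams(noise_sd=0.0)
        _, outcomes, truth = generate_cohort(60, outcome_params=op, seed=31)
        summaries = make_summaries(
            [t.background_true for t in truth.participants],
            [t.response_true for t in truth.participants],
        )
        outcomes = make_outcomes(
            [o.cord_atrophy for o in outcomes]
        )
        fit = fit_inflammation_model(summaries, outcomes)
        assert fit.terms["const"].coef == pytest.approx(5.815, abs=1e-8)
        assert fit.terms["background"].coef == pytest.approx(-4.525e-2, abs=1e-8)
        assert fit.terms["response"].coef == pytest.approx(-1.55e-3, abs=1e-8)
        assert fit.terms["interaction"].coef == pytest.approx(8.91e-6, abs=1e-8)

    def test_standardized_beta_consistent_with_zscored_refit(self):
        """B·sd(x)/sd(y) equals the coefficient of the z-scored regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        bg = rng.lognormal(5, 0.3, 60)
        resp = rng.exponential(2000, 60)
        y = -0.04 * bg - 0.001 * resp + 8e-6 * bg * resp + rng.normal(0, 1, 60)
        fit = fit_inflammation_model(make_summaries(bg, resp), make_outcomes(y))
        X = np.column_stack([bg, resp, bg * resp])
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        res = sm.OLS(yz, sm.add_constant(Xz)).fit()
        for j, name in enumerate(["background", "response", "interaction"]):
            assert fit.terms[name].std_beta == pytest.approx(res.params[j + 1], abs=1e-10)

    def test_f2_consistent_with_oracle_refit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        bg = rng.lognormal(5, 0.3, 50)
        resp = rng.exponential(2000, 50)
        y = -0.02 * bg - 0.0005 * resp + rng.normal(0, 1.0, 50)
        fit = fit_inflammation_model(make_summaries(bg, resp), make_outcomes(y))
        X_full = sm.add_constant(np.column_stack([bg, resp, bg * resp]))
        r2_full = sm.OLS(y, X_full).fit().rsquared
        for j, name in enumerate(["background", "response", "interaction"]):
            r2_red = sm.OLS(y, np.delete(X_full, j + 1, axis=1)).fit().rsquared
            assert fit.terms[name].f2 == pytest.approx(
                cohens_f2(r2_full, min(r2_red, r2_full)), abs=1e-10
            )

    def test_rescaling_predictor_leaves_r2_and_std_beta_invariant(self):
        rng = np.random.default_rng(10)
        bg = rng.lognormal(5, 0.3, 50)
        resp = rng.exponential(2000, 50)
        y = -0.02 * bg - 0.0005 * resp + rng.normal(0, 1.0, 50)
        fit1 = fit_inflammation_model(make_summaries(bg, resp), make_outcomes(y))
        fit2 = fit_inflammation_model(make_summaries(bg, resp / 1000.0), make_outcomes(y))
        assert fit2.r2 == pytest.approx(fit1.r2, abs=1e-10)
        assert fit2.terms["response"].coef == pytest.approx(
            fit1.terms["response"].coef * 1000.0, rel=1e-9
        )
        assert fit2.terms["response"].std_beta == pytest.approx(
            fit1.terms["response"].std_beta, abs=1e-10
        )

    def test_null_betas_small_at_large_n(self):
        rng = np.random.default_rng(11)
        bg = rng.lognormal(5, 0.3, 500)
        resp = rng.exponential(2000, 500)
        y = rng.normal(0, 1, 500)
        fit = fit_inflammation_model(make_summaries(bg, resp), make_outcomes(y))
        for name in ("background", "response", "interaction"):
            assert abs(fit.terms[name].std_beta) < 0.2

    def test_duplicated_predictor_collinearity_error(self):
        rng = np.random.default_rng(12)
        bg = rng.lognormal(5, 0.3, 30)
        resp = bg.copy()  # response duplicates background
        y = rng.normal(0, 1, 30)
        with pytest.raises(ValueError, match="collinear"):
            fit_inflammation_model(make_summaries(bg, resp), make_outcomes(y))

    def test_unmatched_ids_named_in_error(self):
        s = make_summaries([100, 200, 150] * 4, [1000, 2000, 1500] * 4)
        o = make_outcomes(np.arange(12.0), ids=[f"p{i}" for i in range(1, 13)])
        with pytest.raises(ValueError, match="p0"):
            fit_inflammation_model(s, o)

    def test_covariate_model_includes_age_sex(self):
        rng = np.random.default_rng(13)
        n = 60
        bg = rng.lognormal(5, 0.3, n)
        resp = rng.exponential(2000, n)
        age = rng.normal(53, 8, n)
        sex = rng.integers(0, 2, n)
        y = -0.02 * bg + 0.05 * age + rng.normal(0, 1, n)
        fit = fit_inflammation_model(
            make_summaries(bg, resp), make_outcomes(y, age=age, sex=sex),
            covariates=("age", "sex"),
        )
        assert set(fit.terms) == {"const", "background", "response", "interaction", "age", "sex"}
        assert fit.terms["age"].coef == pytest.approx(0.05, abs=3 * fit.terms["age"].se)


class TestStratifiedPrediction:
    def test_tertile_sizes_16_17_for_49(self):
        rng = np.random.default_rng(14)
        low, high = _tertile_bounds(rng.normal(size=49))
        assert low.sum() == 16 and high.sum() == 17

    def test_no_interaction_gives_parallel_curves(self):
        rng = np.random.default_rng(15)
        bg = rng.lognormal(5, 0.3, 60)
        resp = rng.uniform(0, 4000, 60)
        y = -0.02 * bg - 0.0005 * resp + rng.normal(0, 0.5, 60)
        s = make_summaries(bg, resp)
        fit = fit_inflammation_model(s, make_outcomes(y))
        # force a fit whose interaction coefficient is (nearly) zero by
        # construction, then compare stratum slopes of the fitted surface
        curves = stratified_prediction(fit, s, split="median")
        slopes = {}
        for name, df in curves.items():
            slopes[name] = np.polyfit(df["response"], df["predicted"], 1)[0]
        c = fit.terms["interaction"].coef
        bg_means = {name: df["background"].iloc[0] for name, df in curves.items()}
        expected_gap = c * (bg_means["above_median"] - bg_means["below_median"])
        assert slopes["above_median"] - slopes["below_median"] == pytest.approx(
            expected_gap, abs=1e-9
        )

    def test_interaction_moderates_stratum_slopes(self):
        """With the study-like coefficient pattern, the low-background
        stratum slope is more negative than the high-background one."""
        op = OutcomeParams(noise_sd=0.2)
        _, outcomes, truth = generate_cohort(120, outcome_params=op, seed=32)
        s = make_summaries(
            [t.background_true for t in truth.participants],
            [t.response_true for t in truth.participants],
        )
        fit = fit_inflammation_model(s, make_outcomes([o.cord_atrophy for o in outcomes]))
        curves = stratified_prediction(fit, s, split="tertile")
        slope = {
            name: np.polyfit(df["response"], df["predicted"], 1)[0]
            for name, df in curves.items()
        }
        assert slope["lower_tertile"] < slope["upper_tertile"]

    def test_requires_interaction_term(self):
        rng = np.random.default_rng(16)
        bg = rng.lognormal(5, 0.3, 30)
        resp = rng.exponential(2000, 30)
        fit = fit_inflammation_model(make_summaries(bg, resp),
                                     make_outcomes(rng.normal(size=30)))
        fit.terms.pop("interaction")
        with pytest.raises(ValueError, match="interaction"):
            stratified_prediction(fit, make_summaries(bg, resp))
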