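"""Estimator-level checks: exact fixtures, reductions, failure paths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treatbias import (
    PeriodFit,
    ScenarioConfig,
    compose_lifetime,
    estimate_all,
    fit_censored,
    fit_conditional1,
    fit_conditional2,
    fit_conditional3,
    fit_constant,
    fit_linear,
    fit_marginal,
    fit_prior_to_treatment,
    fit_untreated,
    mask_observations,
    scenario_preset,
    simulate_cohort,
    true_gamma,
)
from treatbias.estimators import _as_wide, _slope_fit


# ---------------------------------------------------------------------------
# least-squares backend


def test_fit_linear_exact_interpolation():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
    beta = np.array([1.0, -2.0, 0.5])
    fit = fit_linear(X @ beta, X)
    assert not fit.rank_deficient
    assert np.allclose(fit.beta, beta, atol=1e-10)

    const = fit_linear(np.full(10, 3.0), X)
    assert np.allclose(const.beta[1:], 0.0, atol=1e-10)


def test_fit_linear_matches_normal_equations_and_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
    y = rng.normal(size=10)
    fit = fit_linear(y, X)
    # brute-force normal equations by explicit inversion
    beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ y
    resid = y - X @ beta_oracle
    cov_oracle = (resid @ resid / (10 - 3)) * np.linalg.inv(X.T @ X)
    assert np.allclose(fit.beta, beta_oracle, atol=1e-10)
    assert np.allclose(fit.cov, cov_oracle, atol=1e-10)
    sm_fit = sm.OLS(y, X).fit()
    assert np.allclose(fit.beta, sm_fit.params, atol=1e-10)
    assert np.allclose(fit.cov, sm_fit.cov_params(), atol=1e-10)


def test_fit_linear_flags_singular_design():
    X = np.column_stack([np.ones(6), np.arange(6.0), np.arange(6.0)])
    fit = fit_linear(np.arange(6.0), X)
    assert fit.rank_deficient and fit.cov is None


# ---------------------------------------------------------------------------
# exact fixtures


def test_marginal_perfect_fit(make_cohort):
    G = np.array([0, 1, 2, 0, 1, 2])
    Y = np.column_stack([np.zeros(6), G.astype(float)])
    res = fit_marginal(make_cohort(G, Y))
    assert res.estimate == pytest.approx(1.0, abs=1e-10)
    assert not res.failed


def test_prior_to_treatment_exact_half_slope(make_cohort):
    G = np.array([0, 1, 2, 0, 1, 2])
    Y = np.column_stack([0.5 * G, np.zeros(6)])
    res = fit_prior_to_treatment(make_cohort(G, Y))
    assert res.estimate == pytest.approx(0.5, abs=1e-10)
    assert res.estimand == "lambda_baseline"


def test_conditional2_recovers_noise_free_coefficients(make_cohort):
    # exact interpolation fixture: lagged phenotypes carry independent
    # variation (they are drawn, not generated), so every coefficient is
    # identified and must be recovered to machine precision
    rng = np.random.default_rng(3)
    n = 60
    lam, om0, om1, om2, om3 = (0.4, 0.3, 0.2), (0.1, -0.2, 0.3), -2.0, 1.5, (0.6, 0.7)
    G = rng.integers(0, 3, n).astype(float)
    D = rng.integers(0, 2, (n, 3)).astype(float)
    D[:, 1:] = D[:, :1]  # treatment fixed after baseline
    U = rng.normal(size=(n, 3))
    Y = np.empty((n, 3))
    Y[:, 0] = rng.normal(size=n) + lam[0] * G
    for t in (1, 2):
        Y[:, t] = (
            om0[t] + lam[t] * G + om1 * D[:, t - 1] + om2 * U[:, t - 1]
            + om3[t - 1] * Y[:, t - 1]
        )
    res = fit_conditional2(make_cohort(G, Y, D, U))
    # post-baseline coefficients interpolate exactly; the baseline slope
    # carries the draw noise of Y_0, so compose with its own OLS value
    lam0_hat = np.polyfit(G, Y[:, 0], 1)[0]
    expected = lam[2] + lam[1] * om3[1] + lam0_hat * om3[0] * om3[1]
    assert res.estimate == pytest.approx(expected, abs=1e-8)


# ---------------------------------------------------------------------------
# reductions between strategies


@pytest.fixture(scope="module")
def small_s3a():
    return simulate_cohort(scenario_preset("S3A", 0.5, n_subjects=400, seed=9))


def _per_period_marginal_sum(df):
    wide = _as_wide(df)
    parts = [
        _slope_fit(wide.Y[:, t], [("g", wide.G)], None, wide.n)
        for t in range(1, wide.T + 1)
    ]
    return sum(p[0] for p in parts)


def test_conditional1_without_treated_reduces_to_marginal_fits():
    cfg = scenario_preset("S3A", 0.5, n_subjects=300, seed=4)
    df = simulate_cohort(cfg.replace(randomized=True, a0=-40.0))
    assert (df.treatment == 0).all()
    res = fit_conditional1(df)
    assert res.estimate == pytest.approx(_per_period_marginal_sum(df), abs=1e-10)
    untr = fit_untreated(df)
    assert untr.estimate == pytest.approx(res.estimate, abs=1e-10)


def test_conditional3_without_treated_equals_conditional2():
    cfg = scenario_preset("S3A", 0.5, n_subjects=300, seed=5)
    df = simulate_cohort(cfg.replace(randomized=True, a0=-40.0))
    r2, r3 = fit_conditional2(df), fit_conditional3(df)
    assert r3.estimate == pytest.approx(r2.estimate, abs=1e-10)
    assert r3.std_error == pytest.approx(r2.std_error, abs=1e-10)


def test_constant_zero_correction_is_per_period_marginal(small_s3a):
    res = fit_constant(small_s3a, correction=0.0)
    assert res.estimate == pytest.approx(
        _per_period_marginal_sum(small_s3a), abs=1e-10
    )


def test_censored_without_censoring_matches_least_squares():
    cfg = scenario_preset("S3A", 0.5, n_subjects=300, seed=6)
    df = simulate_cohort(cfg.replace(randomized=True, a0=-40.0))
    res = fit_censored(df)
    assert res.estimate == pytest.approx(_per_period_marginal_sum(df), abs=1e-5)


# ---------------------------------------------------------------------------
# life-time composition


def test_compose_lifetime_two_period_arithmetic():
    # gamma = lambda_1 + lambda_0 * omega3 = 0.3 + 0.4 * 0.5
    fits = [
        PeriodFit(0, 0.4, 0.0, np.zeros((2, 2))),
        PeriodFit(1, 0.3, 0.5, np.zeros((2, 2))),
    ]
    gamma, se = compose_lifetime(fits)
    assert gamma == pytest.approx(0.5)
    assert se == 0.0


def test_compose_lifetime_zero_effects_any_lag():
    fits = [
        PeriodFit(0, 0.0, 0.0, np.zeros((2, 2))),
        PeriodFit(1, 0.0, 0.9, np.zeros((2, 2))),
        PeriodFit(2, 0.0, -0.4, np.zeros((2, 2))),
    ]
    assert compose_lifetime(fits)[0] == 0.0


def test_compose_lifetime_missing_period_raises():
    fits = [
        PeriodFit(0, 0.1, 0.0, np.zeros((2, 2))),
        PeriodFit(2, 0.1, 0.5, np.zeros((2, 2))),
    ]
    with pytest.raises(ValueError, match="period"):
        compose_lifetime(fits)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    lam=st.lists(st.floats(-2, 2), min_size=2, max_size=6),
    om3=st.lists(st.floats(-1, 1), min_size=6, max_size=6),
)
def test_compose_lifetime_matches_effect_recursion(lam, om3):
    # oracle: propagate a unit genotype effect through the Markov chain
    T = len(lam) - 1
    fits = [PeriodFit(0, lam[0], 0.0, np.zeros((2, 2)))]
    fits += [
        PeriodFit(t, lam[t], om3[t - 1], np.zeros((2, 2)))
        for t in range(1, T + 1)
    ]
    eff = lam[0]
    for t in range(1, T + 1):
        eff = lam[t] + om3[t - 1] * eff
    assert compose_lifetime(fits)[0] == pytest.approx(eff, rel=1e-9, abs=1e-9)


def test_delta_se_agrees_with_bootstrap_se():
    ratios = []
    for seed in (21, 22, 23):
        df = simulate_cohort(scenario_preset("S3A", 0.5, seed=seed))
        delta = fit_conditional2(df, se_method="delta")
        boot = fit_conditional2(df, se_method="bootstrap", n_boot=200, seed=1)
        assert delta.estimate == pytest.approx(boot.estimate)
        ratios.append(delta.std_error / boot.std_error)
    assert abs(np.mean(ratios) - 1.0) < 0.15


# ---------------------------------------------------------------------------
# failure paths and invariants


def test_monomorphic_genotype_fails_all_strategies(make_cohort):
    G = np.zeros(20, dtype=int)
    Y = np.random.default_rng(0).normal(size=(20, 2))
    results = estimate_all(make_cohort(G, Y))
    assert all(r.failed for r in results)


def test_everyone_treated_fails_untreated_only(small_s3a):
    df = small_s3a.copy()
    df["treatment"] = 1
    assert fit_untreated(df).failed
    assert not fit_conditional1(df).failed


def test_missing_confounder_fails_conditional_models(small_s3a):
    df = small_s3a.drop(columns=["confounder"])
    assert fit_conditional2(df).failed
    assert fit_conditional3(df).failed
    assert not fit_marginal(df).failed


def test_baseline_only_table_supports_prior_and_marginal(make_cohort):
    G = np.array([0, 1, 2, 0, 1, 2, 1, 1])
    Y = (0.5 * G).reshape(-1, 1)
    df = make_cohort(G, Y)
    assert fit_prior_to_treatment(df).estimate == pytest.approx(0.5)
    assert not fit_marginal(df).failed
    assert fit_conditional1(df).failed
    assert fit_censored(df).failed


def test_result_invariants_on_simulated_cohort(small_s3a):
    for res in estimate_all(small_s3a):
        assert not res.failed
        assert res.ci_low <= res.estimate <= res.ci_high
        assert 0.0 <= res.p_value <= 1.0
        expected = (
            "lambda_baseline"
            if res.strategy == "prior_to_treatment"
            else "gamma_lifetime"
        )
        assert res.estimand == expected


def test_prior_to_treatment_unaffected_by_observation_mask(small_s3a):
    masked = mask_observations(small_s3a, (0, 5))
    a = fit_prior_to_treatment(small_s3a)
    b = fit_prior_to_treatment(masked)
    assert a.estimate == pytest.approx(b.estimate, abs=1e-12)


def test_unknown_strategy_rejected(small_s3a):
    with pytest.raises(ValueError, match="unknown strategy"):
        estimate_all(small_s3a, ["marginal", "mystery"])
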