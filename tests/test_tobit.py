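import math

import numpy as np
import pytest
from scipy import stats

from kanosat.simulate import GeneratorConfig, generate_outcomes
from kanosat.tobit import (
    DeviationOutcome,
    TobitConfig,
    compute_deviations,
    fit_both_models,
    fit_tobit,
    minmax_normalize,
    tobit_loglik,
    vif,
    wald_asymmetry,
    wald_from_summary,
)


# ---------------------------------------------------------------------------
# deviations and attention

@pytest.mark.parametrize(
    "rating,comp,pd,nd",
    [(5, 3.0, 2.0, 0.0), (1, 5.0, 0.0, 4.0), (4, 4.0, 0.0, 0.0), (3, 4.5, 0.0, 1.5)],
)
def test_deviations_are_one_sided_gaps(rating, comp, pd, nd):
    out = compute_deviations([rating], [comp])
    assert out.pd[0] == pytest.approx(pd) and out.nd[0] == pytest.approx(nd)


def test_deviations_validate_inputs():
    with pytest.raises(ValueError, match="ratings"):
        compute_deviations([6], [4.0])
    with pytest.raises(ValueError, match="comprehensive"):
        compute_deviations([4], [0.5])


def test_deviations_stay_in_range_and_one_sided(rng):
    ratings = rng.integers(1, 6, size=500)
    comp = rng.uniform(1, 5, size=500)
    out = compute_deviations(ratings, comp)
    assert ((0 <= out.pd) & (out.pd <= 4)).all()
    assert ((0 <= out.nd) & (out.nd <= 4)).all()
    assert np.all((out.pd == 0) | (out.nd == 0))


def test_minmax_normalize_columns():
    theta = np.array([[0.2, 0.3], [0.4, 0.3], [0.6, 0.3]])
    x, constant = minmax_normalize(theta)
    assert np.allclose(x[:, 0], [0.0, 0.5, 1.0])
    assert np.allclose(x[:, 1], 0.0) and constant.tolist() == [False, True]
    # already spanning the endpoints: unchanged
    y = np.array([[0.0], [0.4], [1.0]])
    x2, _ = minmax_normalize(y)
    assert np.allclose(x2, y)


# ---------------------------------------------------------------------------
# likelihood

def _brute_force_loglik(y, X, beta, sigma, lower, upper):
    """Term-by-term evaluation of the two-limit censored-normal formula."""
    total = 0.0
    for yi, xi in zip(y, X):
        mu = float(np.dot(xi, beta))
        if yi <= lower:
            total += math.log(stats.norm.cdf((lower - mu) / sigma))
        elif yi >= upper:
            # upper-tail mass 1 - Phi evaluated via the survival function,
            # which keeps full precision in the far tail
            total += math.log(stats.norm.sf((upper - mu) / sigma))
        else:
            total += math.log(stats.norm.pdf((yi - mu) / sigma) / sigma)
    return total


# 10-row printed fixture: outcomes include both limits and interior values
FIXTURE_Y = np.array([0.0, 0.0, 0.3, 1.2, 4.0, 2.5, 0.0, 3.9, 4.0, 0.7])
FIXTURE_X = np.array(
    [
        [0.10, 0.80], [0.00, 0.20], [0.30, 0.40], [0.55, 0.10], [0.95, 0.05],
        [0.70, 0.30], [0.05, 0.95], [0.90, 0.20], [1.00, 0.00], [0.45, 0.50],
    ]
)


def test_loglik_matches_brute_force_oracle():
    beta = np.array([2.5, -0.8])
    sigma = 1.3
    ours = tobit_loglik(FIXTURE_Y, FIXTURE_X, beta, sigma, 0.0, 4.0)
    oracle = _brute_force_loglik(FIXTURE_Y, FIXTURE_X, beta, sigma, 0.0, 4.0)
    assert ours == pytest.approx(oracle, abs=1e-10)


def test_loglik_oracle_at_several_parameter_points():
    for beta, sigma in [([0.0, 0.0], 1.0), ([1.0, 1.0], 0.5), ([-1.0, 3.0], 2.0)]:
        ours = tobit_loglik(FIXTURE_Y, FIXTURE_X, np.array(beta), sigma, 0.0, 4.0)
        oracle = _brute_force_loglik(FIXTURE_Y, FIXTURE_X, np.array(beta), sigma, 0.0, 4.0)
        assert ours == pytest.approx(oracle, abs=1e-10)


# ---------------------------------------------------------------------------
# fitting

def test_uncensored_tobit_equals_least_squares(rng):
    n = 300
    x = rng.uniform(0, 1, size=(n, 1))
    y = 1.5 * x[:, 0] + rng.normal(0, 0.2, size=n) + 2.0
    cfg = TobitConfig(lower=-1e6, upper=1e6, include_intercept=True)
    fit = fit_tobit(y, x, cfg)
    X1 = np.column_stack([np.ones(n), x])
    ols, *_ = np.linalg.lstsq(X1, y, rcond=None)
    assert np.allclose(fit.beta, ols, atol=1e-6)
    assert fit.n_left == 0 and fit.n_right == 0
    # ML sigma (no df correction) at the optimum
    resid = y - X1 @ ols
    assert fit.sigma == pytest.approx(float(np.sqrt(np.mean(resid**2))), rel=1e-4)


def test_loglik_at_optimum_beats_ols_start(rng):
    n = 400
    x = rng.uniform(0, 1, size=(n, 2))
    y = np.clip(x @ np.array([3.0, -1.0]) + rng.normal(0, 1, n), 0, 4)
    fit = fit_tobit(y, x)
    beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
    sigma0 = float(np.std(y - x @ beta0))
    assert fit.loglik >= tobit_loglik(y, x, beta0, sigma0, 0, 4)
    assert fit.converged and fit.sigma > 0 and (fit.se > 0).all()


def test_direct_mode_recovery_within_three_se():
    cfg = GeneratorConfig(seed=3)
    rng = np.random.default_rng(42)
    theta = rng.dirichlet(np.full(12, 0.3), size=20000)
    _, dev, extras = generate_outcomes(theta, cfg, mode="direct", seed=7)
    fit_pd, fit_nd = fit_both_models(dev, extras["x"])
    assert np.all(np.abs(fit_pd.beta - cfg.beta_pd_true) < 3 * fit_pd.se)
    assert np.all(np.abs(fit_nd.beta - cfg.beta_nd_true) < 3 * fit_nd.se)


def test_permuting_rows_leaves_estimates_unchanged(rng):
    n = 500
    x = rng.uniform(0, 1, size=(n, 2))
    y = np.clip(x @ np.array([2.0, -1.0]) + rng.normal(0, 1, n), 0, 4)
    fit = fit_tobit(y, x)
    perm = rng.permutation(n)
    fit_p = fit_tobit(y[perm], x[perm])
    assert np.allclose(fit.beta, fit_p.beta, atol=1e-10)
    assert fit.sigma == pytest.approx(fit_p.sigma, abs=1e-10)


def test_all_censored_and_zero_design_rejected(rng):
    x = rng.uniform(0, 1, size=(50, 1))
    with pytest.raises(ValueError, match="censored"):
        fit_tobit(np.zeros(50), x)
    with pytest.raises(ValueError, match="variation"):
        fit_tobit(np.linspace(0.1, 3.9, 50), np.zeros((50, 1)))


def test_censoring_tallies_match_analytic_tail():
    """With a large dissatisfaction effect a predictable fraction of nd*
    draws lands on the upper limit."""
    rng = np.random.default_rng(5)
    n = 40000
    x = rng.uniform(0, 1, size=n)
    beta, sigma = 6.0, 1.0
    nd = np.clip(beta * x + rng.normal(0, sigma, n), 0, 4)
    expected_upper = float(np.mean(1 - stats.norm.cdf((4 - beta * x) / sigma)))
    observed = float(np.mean(nd >= 4))
    se = math.sqrt(expected_upper * (1 - expected_upper) / n)
    assert abs(observed - expected_upper) < 3 * se


# ---------------------------------------------------------------------------
# Wald asymmetry

def test_wald_zero_when_coefficients_equal():
    w = wald_from_summary(1.3, 0.2, 1.3, 0.4)
    assert w.statistic == 0.0 and w.p == 1.0


def test_wald_direct_arithmetic():
    w = wald_from_summary(1.0, 0.1, -1.0, 0.1, mode="difference")
    assert w.statistic == pytest.approx(200.0)
    w2 = wald_from_summary(1.0, 0.1, -1.0, 0.1, mode="sign_flipped_difference")
    assert w2.statistic == 0.0


def test_chi_square_tail_reference():
    from scipy.stats import chi2

    # the p-value reference: W = 3.84 at df 1 sits on the 5% boundary
    assert chi2.sf(3.84, 1) == pytest.approx(0.050, abs=1e-3)
    assert wald_from_summary(1.96, 1.0, 0.0, 1.0).p == pytest.approx(
        chi2.sf(1.96**2 / 2, 1))


def test_wald_symmetric_in_fit_order(rng):
    n = 2000
    x = rng.uniform(0, 1, size=(n, 2))
    pd = np.clip(x @ np.array([1.0, 0.2]) + rng.normal(0, 1, n), 0, 4)
    nd = np.clip(x @ np.array([-0.5, 2.0]) + rng.normal(0, 1, n), 0, 4)
    f1, f2 = fit_both_models(DeviationOutcome(pd, nd), x)
    a = wald_asymmetry(f1, f2, 0, mode="difference")
    b = wald_asymmetry(f2, f1, 0, mode="difference")
    assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_wald_rejects_zero_variance():
    with pytest.raises(ValueError, match="zero variance"):
        wald_from_summary(1.0, 0.0, 2.0, 0.0)


# ---------------------------------------------------------------------------
# VIF

def test_vif_orthogonal_columns_are_one():
    x = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
    report = vif(x)
    assert all(v == pytest.approx(1.0) for v in report.values())


def test_vif_duplicated_column_infinite():
    rng = np.random.default_rng(0)
    col = rng.uniform(0, 1, 50)
    with pytest.warns(RuntimeWarning, match="collinear"):
        report = vif(np.column_stack([col, col, rng.uniform(0, 1, 50)]))
    assert report["x0"] == math.inf and report["x1"] == math.inf


def test_vif_matches_explicit_normal_equations(rng):
    x = rng.uniform(0, 1, size=(200, 3))
    x[:, 2] = 0.6 * x[:, 0] + 0.2 * x[:, 1] + 0.2 * rng.uniform(0, 1, 200)
    report = vif(x)
    for j in range(3):
        yj = x[:, j]
        others = np.column_stack([np.ones(200), np.delete(x, j, axis=1)])
        # solve the normal equations directly as an independent route
        coef = np.linalg.solve(others.T @ others, others.T @ yj)
        resid = yj - others @ coef
        r2 = 1 - (resid @ resid) / np.sum((yj - yj.mean()) ** 2)
        assert report[f"x{j}"] == pytest.approx(1 / (1 - r2), rel=1e-10)
        assert report[f"x{j}"] >= 1.0
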