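"""Block likelihood, Nelder-Mead fitting and the likelihood-ratio test."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from gbdmr.gbeta import GBetaParams, gbeta_sample
from gbdmr.regression import RegressionData, block_negloglik, fit_block, lrt_block


def simulate_from_model(X, gamma0, gamma1, beta_b, rng, L=1):
    """Draw Z from the generalized beta regression model itself."""
    n = X.shape[0]
    eta = np.atleast_1d(gamma0)[None, :] + (X[:, 1:] @ np.atleast_1d(gamma1))[:, None]
    Z = np.empty((n, L))
    alpha = beta_b * np.exp(eta)
    for i in range(n):
        Z[i] = gbeta_sample(1, GBetaParams(alpha[i], beta_b), rng)[0]
    return Z


def small_design(n=60, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n).astype(float)
    x[0], x[1] = 0.0, 1.0          # guarantee both levels
    return np.column_stack([np.ones(n), x])


def test_negloglik_zero_for_uniform_model(rng):
    """gamma_0=0, beta_b=1 makes every alpha_i=1: the uniform density."""
    Z = rng.uniform(0.05, 0.95, size=(40, 1))
    data = RegressionData(Z, small_design(40))
    assert block_negloglik(np.array([0.0, 0.0, 0.0]), data) == pytest.approx(0.0, abs=1e-10)


def test_negloglik_matches_univariate_beta_oracle(rng):
    """L=1 likelihood equals the sum of closed-form beta log-densities."""
    X = small_design(80, seed=1)
    Z = rng.uniform(0.05, 0.95, size=(80, 1))
    data = RegressionData(Z, X)
    gamma0, gamma1, log_b = 0.4, -0.7, np.log(6.0)
    nll = block_negloglik(np.array([gamma0, gamma1, log_b]), data)
    b = np.exp(log_b)
    alpha = b * np.exp(gamma0 + gamma1 * X[:, 1])
    oracle = -stats.beta.logpdf(Z[:, 0], alpha, b).sum()
    assert nll == pytest.approx(oracle, rel=1e-10)


def test_negloglik_invariant_to_row_permutation(rng):
    X = np.column_stack([np.ones(50), rng.normal(size=50)])   # continuous phenotype
    Z = rng.uniform(0.1, 0.9, size=(50, 2))
    theta = np.array([0.2, -0.1, 0.3, np.log(4.0)])
    perm = rng.permutation(50)
    a = block_negloglik(theta, RegressionData(Z, X))
    b = block_negloglik(theta, RegressionData(Z[perm], X[perm]))
    assert a == pytest.approx(b, rel=1e-10)


def test_nonfinite_theta_returns_penalty(rng):
    data = RegressionData(rng.uniform(0.1, 0.9, size=(40, 1)), small_design(40))
    assert block_negloglik(np.array([np.nan, 0.0, 0.0]), data) == np.inf
    assert block_negloglik(np.array([np.inf, 0.0, 0.0]), data) == np.inf


def test_grouped_and_generic_paths_agree(rng):
    """Binary designs use grouped sufficient statistics; results must not change."""
    n = 60
    Xb = small_design(n, seed=3)
    Z = rng.uniform(0.1, 0.9, size=(n, 2))
    theta = np.array([0.3, -0.2, 0.5, np.log(8.0)])
    grouped = RegressionData(Z, Xb)
    assert grouped._grouped
    # jittering the design breaks the grouping without changing it materially
    Xc = Xb.copy()
    Xc[:, 1] += np.arange(n) * 1e-12
    generic = RegressionData(Z, Xc)
    assert not generic._grouped
    assert block_negloglik(theta, grouped) == pytest.approx(
        block_negloglik(theta, generic), rel=1e-9
    )


def test_constant_phenotype_is_rank_deficient(rng):
    Z = rng.uniform(0.1, 0.9, size=(30, 1))
    X = np.column_stack([np.ones(30), np.ones(30)])
    with pytest.raises(ValueError, match="rank"):
        RegressionData(Z, X)


def test_parameter_recovery_from_model_simulation():
    """n=2000 univariate fit recovers (gamma_0, gamma_1, log beta) within 0.1."""
    rng = np.random.default_rng(99)
    n = 2000
    x = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
    X = np.column_stack([np.ones(n), x])
    Z = simulate_from_model(X, [0.5], [0.8], 20.0, rng)
    fit = fit_block(RegressionData(Z, X), seed=1)
    assert fit.converged
    assert fit.gamma0[0] == pytest.approx(0.5, abs=0.1)
    assert fit.gamma_slopes[0] == pytest.approx(0.8, abs=0.1)
    assert fit.log_beta == pytest.approx(np.log(20.0), abs=0.2)


def test_null_fit_never_beats_full_fit(binary_design):
    rng = np.random.default_rng(5)
    Z = simulate_from_model(binary_design, [-0.8, -0.9], [0.0], 40.0, rng, L=2)
    data = RegressionData(Z, binary_design)
    res = lrt_block(data, seed=2)
    diff = res.fit_full.loglik - res.fit_null.loglik
    assert diff >= -1e-6
    assert 0 <= res.statistic < 10            # null truth: typically small


def test_univariate_fit_matches_independent_beta_regression_oracle(binary_design):
    """L=1 ML fit agrees with a separately coded beta-regression MLE to 1e-3.

    The oracle uses scipy's closed-form beta density and a gradient-based
    optimizer — an independent code path from the block likelihood.
    """
    rng = np.random.default_rng(17)
    Z = simulate_from_model(binary_design, [0.3], [0.5], 25.0, rng)
    fit = fit_block(RegressionData(Z, binary_design), seed=3)

    z = Z[:, 0]
    x = binary_design[:, 1]

    def oracle_nll(t):
        g0, g1, log_b = t
        b = np.exp(log_b)
        alpha = b * np.exp(g0 + g1 * x)
        return -stats.beta.logpdf(z, alpha, b).sum()

    res = minimize(oracle_nll, np.array([0.0, 0.0, np.log(10.0)]), method="BFGS")
    assert fit.gamma0[0] == pytest.approx(res.x[0], abs=1e-3)
    assert fit.gamma_slopes[0] == pytest.approx(res.x[1], abs=1e-3)
    assert fit.log_beta == pytest.approx(res.x[2], abs=1e-3)


def test_nelder_mead_agrees_with_powell(binary_design):
    """The optimum must not be an artifact of the optimizer choice."""
    rng = np.random.default_rng(23)
    Z = simulate_from_model(binary_design, [0.2, 0.1], [0.4], 30.0, rng, L=2)
    data = RegressionData(Z, binary_design)
    nm = fit_block(data, seed=4)
    powell = minimize(
        lambda t: block_negloglik(t, data),
        nm.theta() + 0.05,
        method="Powell",
        options={"ftol": 1e-10, "xtol": 1e-8},
    )
    assert -powell.fun == pytest.approx(nm.loglik, abs=1e-4)


def test_shifting_phenotype_changes_only_intercepts(binary_design):
    rng = np.random.default_rng(31)
    Z = simulate_from_model(binary_design, [0.1], [0.6], 30.0, rng)
    data0 = RegressionData(Z, binary_design)
    X_shift = binary_design.copy()
    X_shift[:, 1] += 2.0
    data1 = RegressionData(Z, X_shift)
    r0 = lrt_block(data0, seed=5)
    r1 = lrt_block(data1, seed=5)
    assert r1.statistic == pytest.approx(r0.statistic, abs=1e-3)
    assert r1.fit_full.gamma_slopes[0] == pytest.approx(r0.fit_full.gamma_slopes[0], abs=1e-3)
    assert r1.fit_full.gamma0[0] == pytest.approx(
        r0.fit_full.gamma0[0] - 2.0 * r0.fit_full.gamma_slopes[0], abs=5e-3
    )


def test_strong_effect_gives_tiny_pvalue(binary_design):
    """Signal strength 1 at n=506 is overwhelming evidence."""
    rng = np.random.default_rng(41)
    from gbdmr.simulation import simulate_block_chain

    present = simulate_block_chain(253, 1, 0.35, 0.05, 0.0, seed=rng)
    absent = simulate_block_chain(253, 1, 0.30, 0.05, 0.0, seed=rng)
    Z = np.vstack([present, absent])
    res = lrt_block(RegressionData(Z, binary_design), seed=6)
    assert res.p_value < 1e-6


def test_null_statistic_mean_near_chisq_df(binary_design):
    """200-block sanity band for the chi-square(1) mean under the model's null."""
    rng = np.random.default_rng(53)
    stats_ = []
    for _ in range(200):
        Z = simulate_from_model(binary_design, [-0.85, -0.85], [0.0], 58.0, rng, L=2)
        stats_.append(lrt_block(RegressionData(Z, binary_design), seed=rng).statistic)
    mean = np.mean(stats_)
    assert 0.7 < mean < 1.35      # chi2(1) mean 1, MC SE ~0.1 at 200 reps
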