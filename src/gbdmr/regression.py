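"""Generalized beta regression per CpG block and the likelihood-ratio test.

For block ``b`` with ``L`` CpGs, sample ``i`` contributes a generalized
beta density with shapes ``alpha_il`` and a block-level dispersion
``beta_b`` shared across samples and CpGs.  The mean of each CpG is tied
to the design through the logit link

    logit E(Z_il) = log(alpha_il) - log(beta_b) = gamma_0l + x_i' gamma,

where ``gamma_0l`` is a CpG-specific intercept and the slopes
``gamma_1..gamma_p`` are shared across the block's CpGs.  Inverting the
link gives the unique reparameterization ``alpha_il = beta_b *
exp(gamma_0l + x_i' gamma)`` used by the likelihood.

The phenotype effect (first slope, ``gamma_1``) is tested with a
likelihood-ratio test: twice the log-likelihood gap between the full fit
and the fit constrained to ``gamma_1 = 0``, referred to chi-square with
one degree of freedom.  Optimization uses Nelder-Mead from a
method-of-moments start plus seeded jittered restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

logger = logging.getLogger(__name__)

#: pre-floor LRT statistics below this are declared convergence failures
LRT_FLOOR_TOL = -1e-4


class RegressionData:
    """Aligned response block and design matrix for one block fit.

    Parameters
    ----------
    Z
        ``(n, L)`` beta values in the open interval (0, 1); one column
        per CpG of the block.
    X
        ``(n, p + 1)`` design matrix: first column the intercept (all
        ones), second column the phenotype of interest, remaining
        columns covariates.  Must have full column rank.

    Notes
    -----
    The constructor precomputes the sufficient statistics of the
    log-likelihood.  When the design has few distinct rows (e.g. a
    binary phenotype without continuous covariates) the likelihood is
    accumulated per distinct row, which makes a Nelder-Mead evaluation
    O(G * L) instead of O(n * L).
    """

    def __init__(self, Z, X):
        Z = np.asarray(Z, dtype=float)
        X = np.asarray(X, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.ndim != 2 or X.ndim != 2:
            raise ValueError("Z and X must be 2-D arrays")
        if Z.shape[0] != X.shape[0]:
            raise ValueError("Z and X must have the same number of rows")
        if np.any(Z <= 0.0) or np.any(Z >= 1.0) or not np.all(np.isfinite(Z)):
            raise ValueError("Z values must lie strictly inside (0, 1)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        n, L = Z.shape
        p = X.shape[1] - 1
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("X is rank deficient (e.g. a constant phenotype column)")
        if n <= p + L + 1:
            raise ValueError(f"need n > p + L + 1 samples (n={n}, p={p}, L={L})")

        self.Z = Z
        self.X = X
        self.n = n
        self.L = L
        self.p = p

        log_odds = np.log(Z) - np.log1p(-Z)            # (n, L)
        log1m = np.log1p(-Z).sum(axis=1)               # sum_l log(1 - z)
        log1p_odds = np.log1p((Z / (1.0 - Z)).sum(axis=1))

        uniq, inverse = np.unique(X, axis=0, return_inverse=True)
        G = uniq.shape[0]
        if G <= max(2, n // 4):
            counts = np.bincount(inverse, minlength=G).astype(float)
            t_sum = np.zeros((G, L))
            for l in range(L):
                t_sum[:, l] = np.bincount(inverse, weights=log_odds[:, l], minlength=G)
            self._grouped = True
            self._Xu = uniq
            self._counts = counts
            self._t_sum = t_sum
            self._log1p_odds_sum = np.bincount(inverse, weights=log1p_odds, minlength=G)
        else:
            self._grouped = False
            self._log_odds = log_odds
            self._log1p_odds = log1p_odds
        # parameter-free term of the log-likelihood: -2 * sum_i sum_l log(1 - z_il)
        self._const = -2.0 * log1m.sum()


def block_negloglik(theta, data: RegressionData) -> float:
    """Negative log-likelihood of one block at the flat parameter vector.

    ``theta`` is ordered ``(gamma_01..gamma_0L, gamma_1..gamma_p,
    log beta_b)``.  Non-finite parameter values return ``+inf`` (an
    optimizer-safe penalty) rather than raising.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (data.L + data.p + 1,):
        raise ValueError(f"theta must have length {data.L + data.p + 1}")
    if not np.all(np.isfinite(theta)):
        return np.inf
    L, p = data.L, data.p
    gamma0 = theta[:L]
    slopes = theta[L : L + p]
    log_b = theta[-1]
    if abs(log_b) > 500.0:                 # exp would overflow / degenerate
        return np.inf
    b = np.exp(log_b)

    with np.errstate(over="ignore", invalid="ignore"):
        if data._grouped:
            eta = gamma0[None, :] + (data._Xu[:, 1:] @ slopes)[:, None]   # (G, L)
            if np.any(eta > 500.0):
                return np.inf
            alpha = b * np.exp(eta)
            a_sum = alpha.sum(axis=1)
            c = data._counts
            ll = (
                np.dot(c, gammaln(a_sum + b) - gammaln(b) - gammaln(alpha).sum(axis=1))
                + ((alpha - 1.0) * data._t_sum).sum()
                - ((a_sum + b) * data._log1p_odds_sum).sum()
                + data._const
            )
        else:
            eta = gamma0[None, :] + (data.X[:, 1:] @ slopes)[:, None]     # (n, L)
            if np.any(eta > 500.0):
                return np.inf
            alpha = b * np.exp(eta)
            a_sum = alpha.sum(axis=1)
            ll = (
                (gammaln(a_sum + b) - gammaln(b) - gammaln(alpha).sum(axis=1)).sum()
                + ((alpha - 1.0) * data._log_odds).sum()
                - (a_sum + b) @ data._log1p_odds
                + data._const
            )
    if not np.isfinite(ll):
        return np.inf
    return -float(ll)


@dataclass
class BlockFit:
    """Result of one maximum-likelihood block fit."""

    gamma0: np.ndarray          # L per-CpG intercepts
    gamma_slopes: np.ndarray    # p shared slopes (phenotype first)
    log_beta: float
    loglik: float
    converged: bool
    n_restarts_used: int

    @property
    def beta_b(self) -> float:
        return float(np.exp(self.log_beta))

    def theta(self) -> np.ndarray:
        return np.concatenate([self.gamma0, self.gamma_slopes, [self.log_beta]])


def _moment_start(data: RegressionData) -> np.ndarray:
    """Method-of-moments starting point in the full parameterization."""
    mean = data.Z.mean(axis=0)
    var = data.Z.var(axis=0)
    var = np.minimum(np.maximum(var, 1e-10), mean * (1.0 - mean) * 0.999)
    nu = mean * (1.0 - mean) / var - 1.0   # alpha_hat + beta_hat per CpG
    a_hat = mean * nu
    b_hat = (1.0 - mean) * nu
    log_b0 = float(np.log(b_hat.mean()))
    gamma0 = np.log(a_hat) - log_b0
    return np.concatenate([gamma0, np.zeros(data.p), [log_b0]])


def fit_block(
    data: RegressionData,
    constrain_null: bool = False,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 2,
    extra_inits: Sequence[np.ndarray] | None = None,
    fatol: float = 1e-8,
) -> BlockFit:
    """Maximize the block likelihood by Nelder-Mead with seeded restarts.

    Parameters
    ----------
    data
        The block's response and design.
    constrain_null
        When true the phenotype slope ``gamma_1`` is fixed at 0 and
        removed from the free parameters (the null fit of the LRT).
    seed
        Seed (or generator) for the jittered restarts.
    n_restarts
        Number of additional jittered restarts beyond the
        method-of-moments start.
    extra_inits
        Optional additional full-parameterization starting points (used
        internally to warm-start the full fit from the null optimum).

    Returns
    -------
    BlockFit
        Best fit across all starts.  ``converged`` is false when no
        start produced a finite optimum with optimizer success.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L, p = data.L, data.p
    slope_idx = L          # index of gamma_1 in the full vector

    def pack(full_theta: np.ndarray) -> np.ndarray:
        """Full parameter vector -> free vector under the null constraint."""
        if not constrain_null:
            return np.asarray(full_theta, dtype=float)
        return np.delete(np.asarray(full_theta, dtype=float), slope_idx)

    def unpack(free_theta: np.ndarray) -> np.ndarray:
        if not constrain_null:
            return np.asarray(free_theta, dtype=float)
        return np.insert(np.asarray(free_theta, dtype=float), slope_idx, 0.0)

    def objective(free_theta):
        return block_negloglik(unpack(free_theta), data)

    x0 = _moment_start(data)
    starts = [pack(x0)]
    for _ in range(n_restarts):
        starts.append(pack(x0) + rng.normal(scale=0.2, size=starts[0].size))
    if extra_inits is not None:
        starts.extend(pack(t) for t in extra_inits)

    best = None
    best_success = False
    dim = starts[0].size
    for s in starts:
        res = minimize(
            objective,
            s,
            method="Nelder-Mead",
            options={
                "fatol": fatol,
                "xatol": 1e-6,
                "maxiter": 200 * dim,
                "maxfev": 400 * dim,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
            best_success = bool(res.success) and np.isfinite(res.fun)
        elif res.success and np.isfinite(res.fun) and res.fun <= best.fun + 1e-10:
            best_success = True

    converged = best is not None and np.isfinite(best.fun) and best_success
    if not converged:
        logger.warning("block fit failed to converge after %d start(s)", len(starts))
    full_theta = unpack(best.x)
    return BlockFit(
        gamma0=full_theta[:L].copy(),
        gamma_slopes=full_theta[L : L + p].copy(),
        log_beta=float(full_theta[-1]),
        loglik=-float(best.fun) if np.isfinite(best.fun) else -np.inf,
        converged=converged,
        n_restarts_used=len(starts),
    )


class LrtResult(NamedTuple):
    """Likelihood-ratio test of the phenotype effect in one block."""

    statistic: float
    p_value: float          # NaN when either fit failed to converge
    fit_full: BlockFit
    fit_null: BlockFit


def lrt_block(data: RegressionData, seed: int | np.random.Generator = 0) -> LrtResult:
    """LRT of ``gamma_1 = 0`` for one block.

    Fits the null model first and warm-starts the full fit from the null
    optimum (the models are nested, so the null optimum is a feasible
    full-model point); the statistic ``2 * (loglik_full - loglik_null)``
    is floored at 0 and referred to chi-square with 1 df.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fit_null = fit_block(data, constrain_null=True, seed=rng)
    fit_full = fit_block(
        data, constrain_null=False, seed=rng, extra_inits=[fit_null.theta()]
    )

    raw = 2.0 * (fit_full.loglik - fit_null.loglik)
    converged = fit_full.converged and fit_null.converged
    if np.isfinite(raw) and raw < LRT_FLOOR_TOL:
        warnings.warn(
            f"negative LRT statistic {raw:.3g} indicates a convergence failure",
            RuntimeWarning,
            stacklevel=2,
        )
        converged = False
    statistic = float(max(raw, 0.0)) if np.isfinite(raw) else np.nan
    if converged and np.isfinite(statistic):
        p_value = float(chi2.sf(statistic, df=1))
    else:
        p_value = np.nan
    return LrtResult(statistic=statistic, p_value=p_value, fit_full=fit_full, fit_null=fit_null)
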