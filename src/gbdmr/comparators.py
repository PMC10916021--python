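"""Comparison methods: per-CpG EWAS and a simplified dmrff statistic.

The traditional EWAS regresses each CpG's M-values (log2 odds of the
beta value) on the phenotype by ordinary least squares and tests the
phenotype coefficient with a two-sided t test.

The simplified dmrff statistic combines the per-CpG EWAS effect
estimates of a region by inverse-variance weighting under the known-
sigma condition: with ``Omega = diag(se) R diag(se)`` the region effect
is ``A = (1' Omega^-1 1)^-1 1' Omega^-1 b_hat`` with standard error
``sqrt((1' Omega^-1 1)^-1)`` and a two-sided normal p-value.  This is
the meta-analysis core of dmrff without its candidate-region search and
EWAS-statistic shrinkage.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

#: ridge added to the diagonal when estimating R from data
CORRELATION_RIDGE = 1e-8


def to_m_values(beta_matrix) -> np.ndarray:
    """Convert beta values to M-values, ``M = log2(z / (1 - z))``.

    Strictly increasing in ``z``; inputs must already be clipped away
    from the boundaries {0, 1} (the pipeline clips at 1e-6).
    """
    z = np.asarray(beta_matrix, dtype=float)
    if np.any(z <= 0.0) or np.any(z >= 1.0) or not np.all(np.isfinite(z)):
        raise ValueError("beta values must lie strictly inside (0, 1); clip first")
    return np.log2(z / (1.0 - z))


def m_to_beta(m_matrix) -> np.ndarray:
    """Inverse of :func:`to_m_values`."""
    m = np.asarray(m_matrix, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def ewas_fit(m_matrix, X) -> pd.DataFrame:
    """Per-CpG ordinary least squares of M-values on the design.

    Parameters
    ----------
    m_matrix
        ``(n, m)`` matrix of M-values (CpGs in columns).
    X
        ``(n, p + 1)`` design: intercept, phenotype of interest,
        covariates — the phenotype coefficient (column 1) is the one
        tested.

    Returns
    -------
    DataFrame
        One row per CpG with columns ``estimate``, ``se``, ``t``,
        ``p_value`` (two-sided, ``n - p - 1`` residual df).
    """
    Y = np.asarray(m_matrix, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError("m_matrix and X must have the same number of rows")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix X is rank deficient")

    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = xtx_inv @ X.T @ Y                       # (k, m)
    resid = Y - X @ coefs
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    slope = coefs[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return pd.DataFrame({"estimate": slope, "se": se, "t": t, "p_value": p})


class DmrffStat(NamedTuple):
    estimate: float
    se: float
    z: float
    p_value: float


def dmrff_stat(beta_hats, ses, R) -> DmrffStat:
    """Inverse-variance-weighted region statistic over L CpGs.

    Parameters
    ----------
    beta_hats
        Length-``L`` vector of per-CpG EWAS effect estimates.
    ses
        Length-``L`` vector of their standard errors (all > 0).
    R
        ``(L, L)`` inter-CpG correlation matrix (symmetric, unit
        diagonal).

    Notes
    -----
    When ``Omega`` is numerically singular (e.g. two perfectly
    correlated CpGs) the weights are computed through the Moore-Penrose
    pseudo-inverse, whose limit reproduces the single-effective-CpG
    answer; if even that leaves the statistic undefined, a ``ValueError``
    reporting the condition number is raised.
    """
    b = np.atleast_1d(np.asarray(beta_hats, dtype=float))
    s = np.atleast_1d(np.asarray(ses, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    L = b.size
    if s.shape != (L,) or R.shape != (L, L):
        raise ValueError("beta_hats, ses and R have inconsistent shapes")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("standard errors must be finite and > 0")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("R must have a unit diagonal")

    omega = (s[:, None] * R) * s[None, :]
    ones = np.ones(L)
    cond = np.linalg.cond(omega)
    if cond < 1e10:
        w = np.linalg.solve(omega, ones)
    else:
        w = np.linalg.pinv(omega, hermitian=True) @ ones
    inv_var = float(ones @ w)
    if not np.isfinite(inv_var) or inv_var <= 0:
        raise ValueError(
            f"Omega is not invertible (condition number {cond:.3g}); "
            "the region statistic is undefined"
        )
    estimate = float(w @ b) / inv_var
    se = float(np.sqrt(1.0 / inv_var))
    z = estimate / se
    p = 2.0 * stats.norm.sf(abs(z))
    return DmrffStat(estimate=estimate, se=se, z=float(z), p_value=float(p))


def estimate_block_correlation(m_block) -> np.ndarray:
    """Sample correlation of a block's M-values with a small ridge.

    The ridge (1e-8 on the diagonal before renormalization) guarantees
    invertibility when CpGs are empirically collinear.
    """
    M = np.asarray(m_block, dtype=float)
    if M.ndim != 2:
        raise ValueError("m_block must be 2-D (samples x CpGs)")
    if M.shape[1] == 1:
        return np.ones((1, 1))
    cov = np.cov(M, rowvar=False)
    cov[np.diag_indices_from(cov)] += CORRELATION_RIDGE * np.diag(cov).mean()
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def dmrff_test_block(m_block, X) -> DmrffStat:
    """EWAS each CpG of a block, then combine with :func:`dmrff_stat`."""
    res = ewas_fit(m_block, X)
    R = estimate_block_correlation(m_block)
    return dmrff_stat(res["estimate"].to_numpy(), res["se"].to_numpy(), R)
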