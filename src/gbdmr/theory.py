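"""Closed-form power of the inverse-variance-weighted region statistic.

Under compound-symmetric correlation among the L per-CpG effect
estimates, ``Omega = sigma_n^2 [(1 - rho) I + rho 11']``, the IVW region
effect has standard error

    SE = sqrt( sigma_n^2 (1 + (L - 1) rho) / L ),

the closed form of ``(1' Omega^-1 1)^(-1/2)``.  A two-sided level-alpha
z-test of a true effect ``gamma_1`` then has power

    P(Z > -gamma_1/SE + z_{1-alpha/2}) + P(Z < -gamma_1/SE + z_{alpha/2}).

Because SE grows with rho, the power of the meta-analytic statistic
decays as the CpGs become more correlated: at rho = 1 the L estimates
carry a single effective observation.  This module is the analytic
oracle the simulation harness is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class TheoryParams:
    """Inputs of the analytic power formula.

    Parameters
    ----------
    gamma1
        True phenotype effect on the M-value scale.
    sigma_n
        Per-CpG effect-estimate standard deviation,
        ``sigma / sqrt(sum (x_i - x_bar)^2)``.
    L
        Number of CpGs in the region (>= 1).
    rho
        Common pairwise correlation; positive definiteness requires
        ``rho > -1/(L - 1)``; ``rho = 1`` is allowed as the continuous
        limit (one effective observation).
    alpha_level
        Two-sided test level in (0, 1).
    """

    gamma1: float
    sigma_n: float
    L: int
    rho: float
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_n <= 0 or not np.isfinite(self.sigma_n):
            raise ValueError("sigma_n must be finite and > 0")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.rho > 1.0 or (self.L > 1 and self.rho <= -1.0 / (self.L - 1)):
            raise ValueError(
                "compound-symmetric Omega requires -1/(L-1) < rho <= 1"
            )
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie in (0, 1)")


def compound_symmetry_se(sigma_n: float, L: int, rho: float) -> float:
    """``(1' Omega^-1 1)^(-1/2)`` for compound-symmetric Omega.

    Equals ``sqrt(sigma_n^2 (1 + (L - 1) rho) / L)``: at rho = 0 the L
    estimates average like independent observations (SE ~ 1/sqrt(L)); at
    rho = 1 the SE equals the single-CpG sigma_n.
    """
    TheoryParams(gamma1=0.0, sigma_n=sigma_n, L=L, rho=rho)  # validation
    return float(np.sqrt(sigma_n**2 * (1.0 + (L - 1) * rho) / L))


def theoretical_power(params: TheoryParams) -> float:
    """Exact two-sided power of the IVW region z-test.

    Returns ``alpha_level`` exactly when ``gamma1 = 0`` (the two tails
    sum to alpha).
    """
    se = compound_symmetry_se(params.sigma_n, params.L, params.rho)
    shift = -params.gamma1 / se
    a = params.alpha_level
    upper = norm.sf(shift + norm.ppf(1.0 - a / 2.0))
    lower = norm.cdf(shift + norm.ppf(a / 2.0))
    return float(upper + lower)


def power_curve(
    gammas, rhos, L: int = 2, sigma_n: float = 1.0, alpha_level: float = 0.05
) -> pd.DataFrame:
    """Tidy table of theoretical power over a (gamma, rho) grid."""
    rows = [
        {
            "gamma1": float(g),
            "rho": float(r),
            "L": L,
            "sigma_n": sigma_n,
            "alpha_level": alpha_level,
            "power": theoretical_power(
                TheoryParams(gamma1=float(g), sigma_n=sigma_n, L=L, rho=float(r), alpha_level=alpha_level)
            ),
        }
        for r in np.atleast_1d(rhos)
        for g in np.atleast_1d(gammas)
    ]
    return pd.DataFrame(rows)
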