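"""Synthetic methylation data and the Monte Carlo power/FPR harness.

Single CpG sites are drawn from beta distributions whose shape
parameters are solved from a target (mean, sd).  A binary phenotype
splits samples into present/absent groups (253/253 by default, the Isle
of Wight sample size; an unbalanced 422/84 design is also supported)
that share the standard deviation and differ in mean by
``signal_strength * sd`` — signal strength is the group mean difference
in units of the common SD.  Chains of correlated CpGs are grown one
column at a time: each new column has a fixed Pearson correlation with
its predecessor and the same marginal mean and SD.

The chain uses a Gaussian copula AR step: the predecessor is
normal-scored, mixed with fresh noise at a latent correlation calibrated
(by a Hermite-polynomial expansion of the quantile transform) so the
realized Pearson correlation on the beta scale hits the target, then
mapped back through the Beta(a, b) quantile function.  The copula
preserves the beta marginals exactly; the realized-correlation contract
is +/- 0.05 of the target at n = 506.

The harness runs the detector (on beta values) and the comparators (on
M-values) over Monte Carlo replicates and reports power and false
positive rate as significant-CpG counts over CpG totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import beta as beta_dist

from .comparators import dmrff_stat, estimate_block_correlation, ewas_fit, to_m_values
from .pipeline import MethylationDataset, adjust_pvalues, run_gbdmr

#: base-pair spacing of CpGs inside a block and gap between blocks; the
#: inter-block gap exceeds dmrff's 500 bp window so distance-based
#: regions coincide with the truth blocks in this layout
INTRA_BLOCK_SPACING = 100
INTER_BLOCK_GAP = 10_000

METHODS = ("gbdmr", "ewas", "dmrff_simple")


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario.

    Parameters
    ----------
    n_present, n_absent
        Group sizes of the binary phenotype (253/253 or 422/84 in the
        study designs).  Ignored when ``continuous`` is true.
    baseline_mean, baseline_sd
        Marginal beta-value mean and SD of the absent group; must
        satisfy ``sd^2 < mean * (1 - mean)`` (beta feasibility).
    signal_strength
        Group mean difference in SD units (>= 0); 0 simulates the null.
    rho
        Target adjacent Pearson correlation within a block, in [0, 1).
    block_size
        CpGs per block (>= 1).
    n_blocks
        Total blocks per replicate dataset.
    n_signal_blocks
        How many of the blocks carry the signal; ``None`` means all
        blocks when ``signal_strength > 0`` and none otherwise.
    n_reps
        Monte Carlo replicates (500 in the headline experiments).
    alpha_level, correction
        Significance level and multiplicity mode ("none" = per-test,
        or "bonferroni"/"holm"/"bh" across blocks within a replicate).
    continuous
        Use a standardized continuous phenotype instead of the binary
        groups; the per-sample mean is ``baseline_mean +
        signal_strength * sd * x_i``.
    n_samples
        Total samples in continuous mode.
    """

    n_present: int = 253
    n_absent: int = 253
    baseline_mean: float = 0.3
    baseline_sd: float = 0.05
    signal_strength: float = 0.0
    rho: float = 0.0
    block_size: int = 2
    n_blocks: int = 100
    n_signal_blocks: int | None = None
    n_reps: int = 500
    alpha_level: float = 0.05
    correction: str = "none"
    continuous: bool = False
    n_samples: int = 506
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0 or not 0.0 < self.baseline_mean < 1.0:
            raise ValueError("baseline mean must be in (0,1) and sd > 0")
        if self.baseline_sd**2 >= self.baseline_mean * (1.0 - self.baseline_mean):
            raise ValueError("baseline_sd^2 must be < mean*(1-mean) (beta feasibility)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.block_size < 1 or self.n_blocks < 1 or self.n_reps < 1:
            raise ValueError("block_size, n_blocks and n_reps must be >= 1")
        if self.n_signal_blocks is not None and not 0 <= self.n_signal_blocks <= self.n_blocks:
            raise ValueError("n_signal_blocks must lie in [0, n_blocks]")

    @property
    def n_total(self) -> int:
        return self.n_samples if self.continuous else self.n_present + self.n_absent

    @property
    def signal_blocks(self) -> int:
        if self.n_signal_blocks is not None:
            return self.n_signal_blocks
        return self.n_blocks if self.signal_strength > 0 else 0


def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters with the requested mean and SD.

    ``a = mu * nu``, ``b = (1 - mu) * nu`` with
    ``nu = mu (1 - mu) / sd^2 - 1``; requires ``sd^2 < mu (1 - mu)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie in (0, 1)")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(f"infeasible moments: sd^2={var:.4g} >= mean*(1-mean)={mean*(1-mean):.4g}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _hermite_coefficients(a: float, b: float, n_terms: int = 16, n_nodes: int = 128) -> np.ndarray:
    """Coefficients c_k = E[g(W) He_k(W)] of g(w) = BetaPPF(Phi(w); a, b)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / weights.sum()
    u = np.clip(ndtr(nodes), 1e-300, 1.0 - 1e-16)
    g = beta_dist.ppf(u, a, b)
    he_prev = np.ones_like(nodes)
    he = nodes.copy()
    coeffs = np.empty(n_terms + 1)
    coeffs[0] = np.dot(w, g)
    coeffs[1] = np.dot(w, g * he)
    for k in range(1, n_terms):
        he_prev, he = he, nodes * he - k * he_prev
        coeffs[k + 1] = np.dot(w, g * he)
    return coeffs


def latent_correlation(a: float, b: float, rho: float) -> float:
    """Latent normal correlation giving beta-scale Pearson correlation rho.

    Uses ``Cov(g(W1), g(W2)) = sum_k c_k^2 r^k / k!`` for a bivariate
    normal ``(W1, W2)`` with correlation ``r`` and the Hermite expansion
    of the quantile transform ``g``; solved for ``r`` by bisection.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if rho == 0.0:
        return 0.0
    c = _hermite_coefficients(a, b)
    k = np.arange(1, c.size)
    weights = c[1:] ** 2 / np.array([math.factorial(int(i)) for i in k])
    total = weights.sum()                      # series value at r = 1 (~ Var)

    def gap(r):
        return np.dot(weights, r**k) - rho * total

    return float(brentq(gap, 0.0, 1.0, xtol=1e-10))


def _chain_from_latent(latent: np.ndarray, a, b) -> np.ndarray:
    u = np.clip(ndtr(latent), 1e-15, 1.0 - 1e-15)
    z = beta_dist.ppf(u, a, b)
    return np.clip(z, 1e-12, 1.0 - 1e-12)


def simulate_block_chain(
    n: int,
    block_size: int,
    mean: float,
    sd: float,
    rho: float,
    seed,
) -> np.ndarray:
    """Simulate one block: an AR chain of correlated beta-marginal CpGs.

    Every column is marginally ``Beta(a, b)`` with the requested moments;
    adjacent columns have Pearson correlation ``rho`` (realized within
    +/- 0.05 at n = 506 on average over replicates).
    """
    a, b = beta_params_from_moments(mean, sd)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = latent_correlation(a, b, rho)
    w = rng.standard_normal((n, block_size))
    for l in range(1, block_size):
        w[:, l] = r * w[:, l - 1] + math.sqrt(1.0 - r * r) * w[:, l]
    return _chain_from_latent(w, a, b)


def _chain_per_sample_means(
    n: int, block_size: int, means: np.ndarray, sd: float, rho: float,
    base_mean: float, rng: np.random.Generator,
) -> np.ndarray:
    """Copula chain where each sample has its own marginal mean (continuous mode)."""
    a_base, b_base = beta_params_from_moments(base_mean, sd)
    r = latent_correlation(a_base, b_base, rho)
    ab = np.array([beta_params_from_moments(float(m), sd) for m in means])
    w = rng.standard_normal((n, block_size))
    for l in range(1, block_size):
        w[:, l] = r * w[:, l - 1] + math.sqrt(1.0 - r * r) * w[:, l]
    return _chain_from_latent(w, ab[:, [0]], ab[:, [1]])


@dataclass
class SimulatedDataset:
    """One simulated replicate with its ground truth."""

    beta_matrix: np.ndarray          # (n, m)
    phenotype: np.ndarray            # (n,)
    annotation: pd.DataFrame
    block_cpg_ids: list[list[str]]   # truth blocks, in genomic order
    truth_signal: np.ndarray         # bool per block
    config: SimConfig

    def to_methylation_dataset(self) -> MethylationDataset:
        sample_ids = [f"s{i:04d}" for i in range(self.beta_matrix.shape[0])]
        beta = pd.DataFrame(
            np.clip(self.beta_matrix, 1e-6, 1.0 - 1e-6),
            index=sample_ids,
            columns=self.annotation["cpg_id"].to_numpy(),
        )
        pheno = pd.DataFrame({"phenotype": self.phenotype}, index=sample_ids)
        return MethylationDataset(beta=beta, annotation=self.annotation, phenotypes=pheno)

    @property
    def signal_cpg_ids(self) -> set[str]:
        return {
            c
            for ids, s in zip(self.block_cpg_ids, self.truth_signal)
            if s
            for c in ids
        }

    @property
    def null_cpg_ids(self) -> set[str]:
        return {
            c
            for ids, s in zip(self.block_cpg_ids, self.truth_signal)
            if not s
            for c in ids
        }


def simulate_dataset(config: SimConfig, seed=None) -> SimulatedDataset:
    """Simulate one replicate dataset under ``config``.

    Binary designs draw the present group with mean shifted up by
    ``signal_strength * sd`` (same SD); the continuous extension links
    each sample's mean to a standardized phenotype through the same
    shift.  Blocks are laid on one synthetic chromosome with 100 bp
    intra-block spacing and 10 kb gaps between blocks.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    mu, sd, s = config.baseline_mean, config.baseline_sd, config.signal_strength
    shifted = mu + s * sd
    if not 0.0 < shifted < 1.0 or sd * sd >= shifted * (1.0 - shifted):
        raise ValueError(
            f"shifted mean {shifted:.4g} leaves (0,1) or violates beta feasibility"
        )

    n = config.n_total
    L = config.block_size
    n_signal = config.signal_blocks

    if config.continuous:
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        means = mu + s * sd * x
        if means.min() <= 0 or means.max() >= 1 or (sd**2 >= (means * (1 - means)).min()):
            raise ValueError("continuous phenotype drives a per-sample mean infeasible")
        phenotype = x
    else:
        phenotype = np.concatenate(
            [np.ones(config.n_present), np.zeros(config.n_absent)]
        )

    columns = []
    block_cpg_ids: list[list[str]] = []
    positions = []
    pos = 1_000
    cpg_counter = 0
    truth = np.zeros(config.n_blocks, dtype=bool)
    truth[:n_signal] = True

    for bi in range(config.n_blocks):
        if truth[bi] and s > 0:
            if config.continuous:
                block = _chain_per_sample_means(n, L, means, sd, config.rho, mu, rng)
            else:
                present = simulate_block_chain(
                    config.n_present, L, shifted, sd, config.rho, rng
                )
                absent = simulate_block_chain(
                    config.n_absent, L, mu, sd, config.rho, rng
                )
                block = np.vstack([present, absent])
        else:
            block = simulate_block_chain(n, L, mu, sd, config.rho, rng)
        columns.append(block)
        ids = [f"cg{cpg_counter + j:08d}" for j in range(L)]
        cpg_counter += L
        block_cpg_ids.append(ids)
        positions.extend(pos + j * INTRA_BLOCK_SPACING for j in range(L))
        pos = positions[-1] + INTER_BLOCK_GAP

    beta_matrix = np.hstack(columns)
    annotation = pd.DataFrame(
        {
            "cpg_id": [c for ids in block_cpg_ids for c in ids],
            "chromosome": "chr1",
            "position": positions,
        }
    )
    return SimulatedDataset(
        beta_matrix=beta_matrix,
        phenotype=phenotype,
        annotation=annotation,
        block_cpg_ids=block_cpg_ids,
        truth_signal=truth,
        config=config,
    )


def _significant_cpgs_gbdmr(sim: SimulatedDataset, seed: int) -> set[str]:
    results = run_gbdmr(
        sim.to_methylation_dataset(),
        phenotype_name="phenotype",
        threshold=0.5,
        alpha_level=sim.config.alpha_level,
        correction=sim.config.correction,
        seed=seed,
    )
    return {c for r in results if r.significant for c in r.cpg_ids}


def _significant_cpgs_ewas(sim: SimulatedDataset, X: np.ndarray) -> set[str]:
    M = to_m_values(np.clip(sim.beta_matrix, 1e-6, 1 - 1e-6))
    res = ewas_fit(M, X)
    p_adj = adjust_pvalues(res["p_value"].to_numpy(), method=sim.config.correction)
    cpgs = sim.annotation["cpg_id"].to_numpy()
    return set(cpgs[np.where(p_adj <= sim.config.alpha_level)[0]])


def _significant_cpgs_dmrff(sim: SimulatedDataset, X: np.ndarray) -> set[str]:
    """Simplified dmrff on the contiguity blocks (= 500 bp windows here)."""
    M = to_m_values(np.clip(sim.beta_matrix, 1e-6, 1 - 1e-6))
    res = ewas_fit(M, X)
    est = res["estimate"].to_numpy()
    se = res["se"].to_numpy()
    pvals = []
    offset = 0
    for ids in sim.block_cpg_ids:
        L = len(ids)
        idx = slice(offset, offset + L)
        R = estimate_block_correlation(M[:, idx])
        pvals.append(dmrff_stat(est[idx], se[idx], R).p_value)
        offset += L
    p_adj = adjust_pvalues(np.array(pvals), method=sim.config.correction)
    out: set[str] = set()
    for ids, pa in zip(sim.block_cpg_ids, p_adj):
        if np.isfinite(pa) and pa <= sim.config.alpha_level:
            out.update(ids)
    return out


def estimate_power_fpr(
    config: SimConfig,
    methods: Sequence[str] = METHODS,
) -> pd.DataFrame:
    """Monte Carlo power and false positive rate per method.

    Per replicate the harness simulates one dataset, runs each requested
    method (the detector on beta values; EWAS and the simplified dmrff
    on M-values) and counts significant CpGs among truth-signal blocks
    (power numerator) and truth-null blocks (FPR numerator), each over
    the corresponding CpG total.  Replicate-level means and Monte Carlo
    standard errors are reported; the run is fully reproducible from
    ``config.seed``.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    power_reps = {m: [] for m in methods}
    fpr_reps = {m: [] for m in methods}

    for rep in range(config.n_reps):
        rep_seed = np.random.SeedSequence(entropy=config.seed, spawn_key=(rep,))
        sim = simulate_dataset(config, seed=np.random.default_rng(rep_seed))
        X = np.column_stack([np.ones(sim.phenotype.size), sim.phenotype])
        signal_ids = sim.signal_cpg_ids
        null_ids = sim.null_cpg_ids
        rep_int_seed = int(rep_seed.generate_state(1)[0] % (2**31))

        for m in methods:
            if m == "gbdmr":
                sig = _significant_cpgs_gbdmr(sim, seed=rep_int_seed)
            elif m == "ewas":
                sig = _significant_cpgs_ewas(sim, X)
            else:
                sig = _significant_cpgs_dmrff(sim, X)
            if signal_ids:
                power_reps[m].append(len(sig & signal_ids) / len(signal_ids))
            if null_ids:
                fpr_reps[m].append(len(sig & null_ids) / len(null_ids))

    def summarize(values: list[float]) -> tuple[float, float]:
        if not values:
            return np.nan, np.nan
        arr = np.asarray(values)
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
        return float(arr.mean()), se

    rows = []
    for m in methods:
        power, power_se = summarize(power_reps[m])
        fpr, fpr_se = summarize(fpr_reps[m])
        rows.append(
            {
                "method": m,
                "power": power,
                "false_positive_rate": fpr,
                "power_mc_se": power_se,
                "fpr_mc_se": fpr_se,
                "n_reps": config.n_reps,
            }
        )
    return pd.DataFrame(rows)
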