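"""Synthetic-data generator and the Monte Carlo power/FPR harness."""

import numpy as np
import pytest
from scipy import stats

from gbdmr.simulation import (
    SimConfig,
    beta_params_from_moments,
    estimate_power_fpr,
    latent_correlation,
    simulate_block_chain,
    simulate_dataset,
)


@pytest.mark.parametrize(
    "mean, sd, expected",
    [
        (0.5, np.sqrt(1.0 / 12.0), (1.0, 1.0)),     # the uniform
        (0.3, 0.05, (24.9, 58.1)),                  # nu = 0.21/0.0025 - 1 = 83
    ],
)
def test_beta_params_from_moments(mean, sd, expected):
    a, b = beta_params_from_moments(mean, sd)
    assert a == pytest.approx(expected[0], rel=1e-9)
    assert b == pytest.approx(expected[1], rel=1e-9)
    # round trip: the resulting beta law has the requested moments
    assert stats.beta.mean(a, b) == pytest.approx(mean)
    assert stats.beta.std(a, b) == pytest.approx(sd)


def test_beta_params_infeasible_moments():
    with pytest.raises(ValueError, match="infeasible"):
        beta_params_from_moments(0.5, 0.6)


def test_chain_rho_zero_is_independent():
    rs = []
    for rep in range(100):
        z = simulate_block_chain(506, 2, 0.3, 0.05, 0.0, seed=rep)
        rs.append(np.corrcoef(z[:, 0], z[:, 1])[0, 1])
    assert abs(np.mean(rs)) < 0.05
    assert latent_correlation(*beta_params_from_moments(0.3, 0.05), 0.0) == 0.0


def test_chain_realized_correlation_hits_target():
    """rho=0.8, L=3: mean realized adjacent r within [0.75, 0.85] over 100 reps."""
    rs = []
    for rep in range(100):
        z = simulate_block_chain(506, 3, 0.3, 0.05, 0.8, seed=rep)
        rs.append(np.corrcoef(z[:, 0], z[:, 1])[0, 1])
        rs.append(np.corrcoef(z[:, 1], z[:, 2])[0, 1])
    assert 0.75 < np.mean(rs) < 0.85


def test_chain_preserves_beta_marginals_downstream():
    """The copula AR step leaves column 3 marginally Beta(a, b)."""
    a, b = beta_params_from_moments(0.3, 0.05)
    z = simulate_block_chain(10_000, 3, 0.3, 0.05, 0.8, seed=1)
    assert stats.kstest(z[:, 2], stats.beta(a, b).cdf).pvalue > 0.01


def test_chain_columns_share_moments():
    z = simulate_block_chain(50_000, 4, 0.4, 0.07, 0.6, seed=2)
    np.testing.assert_allclose(z.mean(axis=0), 0.4, atol=0.01)
    np.testing.assert_allclose(z.std(axis=0), 0.07, atol=0.005)


def test_dataset_null_groups_share_distribution():
    config = SimConfig(signal_strength=0.0, rho=0.5, block_size=2, n_blocks=40, seed=9)
    sim = simulate_dataset(config)
    present = sim.beta_matrix[sim.phenotype == 1]
    absent = sim.beta_matrix[sim.phenotype == 0]
    assert abs(present.mean() - absent.mean()) < 0.005
    assert not sim.truth_signal.any()


def test_dataset_signal_shifts_present_group_mean():
    """signal 1 at mu=0.3, sd=0.05: present mean 0.35, absent 0.30."""
    config = SimConfig(signal_strength=1.0, rho=0.0, block_size=2, n_blocks=60, seed=10)
    sim = simulate_dataset(config)
    present = sim.beta_matrix[sim.phenotype == 1]
    absent = sim.beta_matrix[sim.phenotype == 0]
    assert present.mean() == pytest.approx(0.35, abs=0.003)
    assert absent.mean() == pytest.approx(0.30, abs=0.003)
    assert sim.truth_signal.all()


def test_unbalanced_design_counts():
    config = SimConfig(n_present=422, n_absent=84, block_size=1, n_blocks=5, seed=3)
    sim = simulate_dataset(config)
    assert int(sim.phenotype.sum()) == 422
    assert int((sim.phenotype == 0).sum()) == 84


def test_infeasible_shift_raises():
    config = SimConfig(baseline_mean=0.9, baseline_sd=0.05, signal_strength=3.0)
    with pytest.raises(ValueError, match="feasib|leaves"):
        simulate_dataset(config)


def test_continuous_phenotype_mode():
    config = SimConfig(
        continuous=True, n_samples=300, signal_strength=0.5, rho=0.6,
        block_size=2, n_blocks=10, seed=4,
    )
    sim = simulate_dataset(config)
    assert sim.phenotype.shape == (300,)
    assert sim.phenotype.mean() == pytest.approx(0.0, abs=1e-9)
    # methylation tracks the phenotype in signal blocks
    r = np.corrcoef(sim.phenotype, sim.beta_matrix[:, 0])[0, 1]
    assert r > 0.2


def test_annotation_layout_contiguous_blocks():
    config = SimConfig(block_size=3, n_blocks=4, seed=5)
    sim = simulate_dataset(config)
    assert len(sim.annotation) == 12
    pos = sim.annotation["position"].to_numpy()
    gaps = np.diff(pos)
    assert (gaps[[0, 1, 3, 4]] == 100).all()       # intra-block spacing
    assert (gaps[[2, 5]] > 500).all()              # inter-block gaps exceed 500 bp


def test_null_fpr_matches_alpha_in_per_test_mode():
    """With no signal anywhere, per-CpG FPR sits near the test level."""
    config = SimConfig(
        signal_strength=0.0, rho=0.0, block_size=1, n_blocks=60,
        n_reps=10, correction="none", alpha_level=0.05, seed=21,
    )
    table = estimate_power_fpr(config, methods=("ewas",)).set_index("method")
    fpr = table.loc["ewas", "false_positive_rate"]
    se = table.loc["ewas", "fpr_mc_se"]
    assert abs(fpr - 0.05) < 3 * max(se, 0.01)


def test_power_nondecreasing_in_signal_strength():
    """All three methods gain power as the group separation grows."""
    powers = {}
    for s in (0.15, 0.5):
        config = SimConfig(
            signal_strength=s, rho=0.6, block_size=2, n_blocks=12,
            n_reps=8, correction="none", seed=31,
        )
        t = estimate_power_fpr(config).set_index("method")
        powers[s] = t
    for m in ("gbdmr", "ewas", "dmrff_simple"):
        lo, hi = powers[0.15].loc[m], powers[0.5].loc[m]
        slack = 2 * np.hypot(lo["power_mc_se"], hi["power_mc_se"])
        assert hi["power"] >= lo["power"] - slack


def test_harness_reproducible_from_seed():
    config = SimConfig(signal_strength=0.4, rho=0.5, block_size=2, n_blocks=6,
                       n_reps=3, correction="none", seed=77)
    t1 = estimate_power_fpr(config, methods=("ewas", "dmrff_simple"))
    t2 = estimate_power_fpr(config, methods=("ewas", "dmrff_simple"))
    assert t1.equals(t2)


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown method"):
        estimate_power_fpr(SimConfig(n_reps=1), methods=("magic",))
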