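"""Synthetic-trial generator: determinism, calibration and recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenodiv import (
    DiversityTrial,
    GerminationModel,
    SimulationConfig,
    TraitSpec,
    anova_crd,
    genetic_parameters,
    ground_truth,
    simulate_germination,
    simulate_trait_table,
)
from phenodiv.physiology import aggregate_replicates


def one_trait_config(sigma2_g, sigma2_e, seed, n_genotypes=20, k=4, mean=10.0):
    return SimulationConfig(
        traits=(TraitSpec("y", mean, sigma2_g, sigma2_e),),
        n_genotypes=n_genotypes,
        n_replicates=k,
        rng_seed=seed,
    )


def test_same_seed_gives_identical_tables():
    config = one_trait_config(1.0, 0.5, seed=9)
    t1 = simulate_trait_table(config).data
    t2 = simulate_trait_table(config).data
    pd.testing.assert_frame_equal(t1, t2)
    g1 = simulate_germination(config)
    g2 = simulate_germination(config)
    pd.testing.assert_frame_equal(g1, g2)


def test_different_seed_differs():
    a = simulate_trait_table(one_trait_config(1.0, 0.5, seed=1)).data
    b = simulate_trait_table(one_trait_config(1.0, 0.5, seed=2)).data
    assert not np.allclose(a["value"], b["value"])


def test_no_signal_case_equalizes_expected_mean_squares():
    """With sigma2_g = 0 the genotype and residual mean squares estimate the
    same quantity and Vg truncates to 0 in most runs."""
    truncated = 0
    ratio_sum = 0.0
    n_runs = 200
    for seed in range(n_runs):
        config = one_trait_config(0.0, 1.0, seed=seed)
        a = anova_crd(simulate_trait_table(config), "y")
        gp = genetic_parameters(a)
        ratio_sum += a.QMg / a.QMr
        truncated += gp.Vg == 0.0
    assert ratio_sum / n_runs == pytest.approx(1.0, abs=0.15)
    assert truncated / n_runs >= 0.4


def test_h2_recovery_monte_carlo():
    """1000 simulated 20x4 trials at the high-repeatability regime
    (sigma2_g=0.57, sigma2_e=0.09): mean estimated h2 within 0.03 of 0.962."""
    h2 = []
    for seed in range(1000):
        config = one_trait_config(0.57, 0.09, seed=seed)
        a = anova_crd(simulate_trait_table(config), "y")
        h2.append(genetic_parameters(a).h2_pct / 100.0)
    truth = 0.57 / (0.57 + 0.09 / 4)
    assert truth == pytest.approx(0.962, abs=0.001)
    assert np.mean(h2) == pytest.approx(truth, abs=0.03)


def test_genotype_mean_variance_converges():
    """Var of genotype means -> sigma2_g + sigma2_e/k as n_genotypes grows."""
    config = one_trait_config(2.0, 1.0, seed=3, n_genotypes=2000)
    means = simulate_trait_table(config).genotype_means(["y"])["y"]
    expected = 2.0 + 1.0 / 4
    assert means.var(ddof=1) == pytest.approx(expected, rel=0.05)


class TestGroundTruth:
    def test_zero_signal_gives_zero_h2(self):
        gt = ground_truth(one_trait_config(0.0, 1.0, seed=0))
        assert gt.loc["y", "h2_pct"] == 0.0

    def test_h2_algebra(self):
        gt = ground_truth(one_trait_config(3.0 * 1.0 / 4, 1.0, seed=0))
        assert gt.loc["y", "h2_pct"] == pytest.approx(75.0)

    def test_cvg_hand_arithmetic(self):
        gt = ground_truth(one_trait_config(4.0, 1.0, seed=0, mean=10.0))
        assert gt.loc["y", "CVg_pct"] == pytest.approx(100.0 * 2.0 / 10.0)
        assert gt.loc["y", "CVe_pct"] == pytest.approx(100.0 * 1.0 / 10.0)


class TestGermination:
    def germ_config(self, **kwargs):
        base = dict(
            seeds_per_replicate=50,
            n_days=21,
            p_germ_mean=0.9,
            p_germ_genotype_sd=0.0,
            time_mean=5.0,
            time_sd=1.0,
            time_genotype_sd=0.0,
        )
        base.update(kwargs)
        return SimulationConfig(
            traits=(TraitSpec("y", 1.0, 0.0, 1.0),),
            n_genotypes=6,
            n_replicates=4,
            germination=GerminationModel(**base),
            rng_seed=11,
        )

    def test_degenerate_timing_puts_all_seeds_on_one_day(self):
        config = self.germ_config(p_germ_mean=1.0 - 1e-12, time_sd=0.0, time_mean=5.0)
        germ = simulate_germination(config)
        on5 = germ[germ["day"] == 5].groupby(["genotype", "replicate"])["count"].sum()
        assert (on5 == 50).all()
        assert germ[germ["day"] != 5]["count"].sum() == 0

    def test_zero_probability_gives_no_counts(self):
        config = self.germ_config(p_germ_mean=1e-12)
        germ = simulate_germination(config)
        assert germ["count"].sum() == 0

    def test_counts_bounded_by_seeds_sown(self):
        germ = simulate_germination(self.germ_config(p_germ_genotype_sd=0.8,
                                                     time_genotype_sd=1.0))
        totals = germ.groupby(["genotype", "replicate"])["count"].sum()
        assert (totals <= 50).all()

    def test_germination_fraction_within_binomial_interval(self):
        """Per-replicate G% scatters around p as Binomial(50, p)."""
        config = self.germ_config(p_germ_mean=0.8)
        germ = simulate_germination(config)
        totals = germ.groupby(["genotype", "replicate"])["count"].sum()
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 50, 0.8)
        assert totals.between(lo, hi).mean() > 0.95
        assert totals.mean() / 50 == pytest.approx(0.8, abs=0.05)

    def test_derived_mgt_tracks_timing_mean(self):
        config = self.germ_config(time_mean=7.0, time_sd=0.5)
        tidy = aggregate_replicates(simulate_germination(config))
        mgt = tidy[tidy["trait"] == "MGT"]["value"]
        assert mgt.mean() == pytest.approx(7.0, abs=0.3)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        TraitSpec("y", 1.0, -0.1, 1.0)
    with pytest.raises(ValueError):
        TraitSpec("y", 1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        SimulationConfig(traits=(TraitSpec("y", 1.0, 1.0, 1.0),), n_genotypes=1)
    with pytest.raises(ValueError):
        GerminationModel(p_germ_mean=1.5)
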