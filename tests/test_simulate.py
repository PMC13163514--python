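"""Synthetic populations, trait architectures, trials and GBS noise."""

import numpy as np
import pandas as pd
import pytest

from lupings.qc import compute_stats, filter_matrix
from lupings.simulate import (
    SimulationConfig,
    _scaled_genetic_values,
    add_gbs_noise,
    simulate_factorial_cross_population,
    simulate_genotype_means,
    simulate_landrace_collection,
    simulate_trait_architecture,
    simulate_trial,
)
from lupings.trial import detect_crossover, lsd_value, plots_to_frame


class TestFactorialCross:
    def test_line_and_cross_counts(self, tiny_config):
        pop = simulate_factorial_cross_population(tiny_config, lines_per_cross=45)
        assert pop.n_genotypes == 720
        assert len(set(pop.cross_labels)) == 16

    def test_each_parent_contributes_equally(self, small_lines):
        crosses = pd.Series(small_lines.cross_labels)
        a_counts = crosses.str.split("x").str[0].value_counts()
        assert (a_counts == a_counts.iloc[0]).all()

    def test_residual_heterozygosity_matches_ssd_expectation(self):
        """Het at loci segregating in the F1 is (1/2)^generations."""
        het_calls, seg_calls = 0, 0
        for seed in range(10):
            config = SimulationConfig(seed=seed, n_markers=150)
            pop = simulate_factorial_cross_population(
                config, lines_per_cross=10, inbreeding_generations=5
            )
            # loci where the line is not fixed for either parent allele were
            # heterozygous in the F1; count residual hets among all calls at
            # loci polymorphic within the cross
            for cross in sorted(set(pop.cross_labels)):
                rows = [i for i, c in enumerate(pop.cross_labels) if c == cross]
                block = pop.dosage[rows]
                segregating = (block != block[0]).any(axis=0) | (block[0] == 1)
                seg_calls += segregating.sum() * len(rows)
                het_calls += (block[:, segregating] == 1).sum()
        p = 1 / 32
        se = np.sqrt(p * (1 - p) / seg_calls)
        assert het_calls / seg_calls == pytest.approx(p, abs=3 * se)

    def test_same_seed_byte_identical(self, tiny_config):
        a = simulate_factorial_cross_population(tiny_config, lines_per_cross=4)
        b = simulate_factorial_cross_population(tiny_config, lines_per_cross=4)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        assert a.genotype_ids == b.genotype_ids

    def test_invalid_counts_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            simulate_factorial_cross_population(tiny_config, lines_per_cross=0)


class TestLandraceCollection:
    def test_default_sizes(self):
        config = SimulationConfig(seed=2, n_markers=100)
        pop = simulate_landrace_collection(config)
        assert pop.n_genotypes == 452
        assert len(set(pop.accession_ids)) == 113

    def test_single_accession_degenerate(self):
        config = SimulationConfig(seed=3, n_markers=100)
        pop = simulate_landrace_collection(config, 1, 4)
        assert len(set(pop.accession_ids)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_within_accession_identity_exceeds_between(self, seed):
        config = SimulationConfig(seed=seed, n_markers=200)
        pop = simulate_landrace_collection(config, n_accessions=15)
        same = (pop.dosage[:, None, :] == pop.dosage[None, :, :]).mean(axis=2)
        acc = np.array(pop.accession_ids)
        within_mask = (acc[:, None] == acc[None, :]) & ~np.eye(len(acc), dtype=bool)
        between_mask = acc[:, None] != acc[None, :]
        assert same[within_mask].mean() > same[between_mask].mean()


class TestTraitArchitecture:
    def test_zero_qtl_null_architecture(self):
        config = SimulationConfig(seed=1, n_markers=50, qtl_count={"grain_yield": 0})
        arch = simulate_trait_architecture(config, "grain_yield")
        assert not arch.effects.any()

    def test_flowering_major_genes_dominate_variance(self, tiny_config, small_lines):
        arch = simulate_trait_architecture(tiny_config, "flowering_time")
        assert len(arch.major_indices) == tiny_config.major_gene_count
        centered = small_lines.dosage - small_lines.dosage.mean(axis=0)
        total = centered @ arch.effects
        majors_only = centered[:, arch.major_indices] @ arch.effects[arch.major_indices]
        share = majors_only.var() / total.var()
        assert share >= 0.5

    def test_fixed_seed_identical_qtl(self, tiny_config):
        a = simulate_trait_architecture(tiny_config, "grain_yield")
        b = simulate_trait_architecture(tiny_config, "grain_yield")
        np.testing.assert_array_equal(a.qtl_indices, b.qtl_indices)
        np.testing.assert_array_equal(a.effects, b.effects)

    def test_qtl_exceeding_markers_rejected(self):
        config = SimulationConfig(seed=1, n_markers=10, qtl_count={"grain_yield": 11})
        with pytest.raises(ValueError):
            simulate_trait_architecture(config, "grain_yield")


def _architectures(config):
    traits = [
        "grain_yield", "straw_biomass", "flowering_time",
        "maturity_time", "plant_height", "seed_weight",
    ]
    return {t: simulate_trait_architecture(config, t) for t in traits}


class TestTrial:
    def test_noise_free_replicates_identical(self):
        config = SimulationConfig(
            seed=5, n_markers=100, gei_sd_water=0.0, gei_sd_soil=0.0,
            gei_sd_interaction=0.0, crossover_pairs=0, block_sd=0.0,
            plot_error_sd=0.0,
        )
        pop = simulate_factorial_cross_population(config, lines_per_cross=2)
        plots = simulate_trial(pop, _architectures(config), config)
        df = plots_to_frame(plots)
        spread = df.groupby(["genotype", "water", "soil", "trait"])["value"].agg(
            lambda v: v.max() - v.min()
        )
        assert (spread == 0).all()

    def test_noise_free_genotype_means_equal_genetic_values(self):
        config = SimulationConfig(
            seed=6, n_markers=100, gei_sd_water=0.0, gei_sd_soil=0.0,
            gei_sd_interaction=0.0, crossover_pairs=0, block_sd=0.0,
            plot_error_sd=0.0,
        )
        pop = simulate_factorial_cross_population(config, lines_per_cross=2)
        arch = _architectures(config)
        plots = simulate_trial(pop, arch, config)
        df = plots_to_frame(plots)
        yields = df[df["trait"] == "grain_yield"].groupby("genotype")["value"].mean()
        gv = pd.Series(
            _scaled_genetic_values(pop, arch["grain_yield"], "grain_yield"),
            index=pop.genotype_ids,
        )
        np.testing.assert_allclose(yields.loc[gv.index], gv, atol=1e-9)

    def test_heritability_recovered_within_band(self):
        """ANOVA-recovered h2 of genotype means near the 0.6 target."""
        config = SimulationConfig(
            seed=7, n_markers=200, heritability={"grain_yield": 0.6},
            crossover_pairs=0,
        )
        pop = simulate_factorial_cross_population(config, lines_per_cross=10)
        pop = pop.subset(genotypes=np.arange(150))
        plots = simulate_trial(pop, _architectures(config), config)
        h2 = _recovered_h2(plots, config.n_blocks)
        assert 0.45 <= h2 <= 0.75

    def test_heritability_recovery_mean_over_seeds(self):
        """Across 20 seeds the mean recovered h2 is within 0.05 of target."""
        values = []
        for seed in range(20):
            config = SimulationConfig(
                seed=seed, n_markers=120, heritability={"grain_yield": 0.6},
                crossover_pairs=0,
            )
            pop = simulate_factorial_cross_population(config, lines_per_cross=10)
            pop = pop.subset(genotypes=np.arange(150))
            arch = {"grain_yield": simulate_trait_architecture(config, "grain_yield")}
            plots = simulate_trial(
                pop, arch, config, traits=["grain_yield"]
            )
            values.append(_recovered_h2(plots, config.n_blocks))
        assert np.mean(values) == pytest.approx(0.6, abs=0.05)

    def test_implanted_crossover_pairs_detected(self):
        config = SimulationConfig(
            seed=8, n_markers=150, crossover_pairs=2,
            heritability={"grain_yield": 0.6},
        )
        pop = simulate_factorial_cross_population(config, lines_per_cross=5)
        pop = pop.subset(genotypes=np.arange(12))
        plots = simulate_trial(
            pop, _architectures(config), config, traits=["grain_yield"]
        )
        df = plots_to_frame(plots)
        df = df[df["trait"] == "grain_yield"]
        means = df.pivot_table(
            index="genotype", columns="water", values="value", aggfunc="mean"
        )
        resid = df.groupby(["genotype", "water", "soil"])["value"].transform("mean")
        ms_err = ((df["value"] - resid) ** 2).sum() / (len(df) - 12 * 4)
        lsd = lsd_value(ms_err, len(df) - 12 * 4, 2 * config.n_blocks)
        assert len(detect_crossover(means, lsd)) >= 2

    def test_missing_architecture_rejected(self, tiny_config, small_lines):
        with pytest.raises(ValueError, match="architecture"):
            simulate_trial(small_lines, {}, tiny_config, traits=["grain_yield"])


def _recovered_h2(plots, r):
    """One-way ANOVA variance components in the favorable/sandy environment."""
    df = plots_to_frame(plots)
    df = df[
        (df["trait"] == "grain_yield")
        & (df["water"] == "favorable")
        & (df["soil"] == "sandy_loam")
    ]
    g = df["genotype"].nunique()
    means = df.groupby("genotype")["value"].mean()
    grand = df["value"].mean()
    ms_g = r * ((means - grand) ** 2).sum() / (g - 1)
    fitted = df["genotype"].map(means)
    ms_e = ((df["value"] - fitted) ** 2).sum() / (g * (r - 1))
    sigma_g = (ms_g - ms_e) / r
    return sigma_g / (sigma_g + ms_e / r)


class TestGenotypeMeans:
    def test_target_heritability_realized(self):
        config = SimulationConfig(
            seed=9, n_markers=200, heritability={"grain_yield": 0.6}
        )
        pop = simulate_factorial_cross_population(config, lines_per_cross=20)
        arch = simulate_trait_architecture(config, "grain_yield")
        gv = _scaled_genetic_values(pop, arch, "grain_yield")
        y = simulate_genotype_means(pop, arch, config)
        r2 = np.corrcoef(y, gv)[0, 1] ** 2
        assert r2 == pytest.approx(0.6, abs=0.1)


class TestGbsNoise:
    def test_zero_rates_identity(self, small_lines):
        config = SimulationConfig(
            seed=1, n_markers=120,
            missing_rate_marker_range=(0.0, 0.0),
            missing_rate_genotype_range=(0.0, 0.0), het_rate=0.0,
        )
        noisy = add_gbs_noise(small_lines, config)
        np.testing.assert_array_equal(noisy.dosage, small_lines.dosage)

    def test_planted_bad_markers_fail_filter_exactly(self, small_lines):
        config = SimulationConfig(
            seed=4, n_markers=120,
            missing_rate_marker_range=(0.0, 0.0),
            missing_rate_genotype_range=(0.0, 0.0), het_rate=0.0,
        )
        bad = small_lines.marker_ids[:10]
        noisy = add_gbs_noise(
            small_lines, config, bad_marker_ids=bad,
            bad_marker_rate_range=(0.4, 0.5),
        )
        stats = compute_stats(noisy)
        failing = set(stats.marker_missing_rate.index[stats.marker_missing_rate >= 0.3])
        assert failing == set(bad)

    def test_fixed_seed_identical_noise(self, small_lines, tiny_config):
        a = add_gbs_noise(small_lines, tiny_config)
        b = add_gbs_noise(small_lines, tiny_config)
        np.testing.assert_array_equal(a.dosage, b.dosage)

    def test_dosage_domain_preserved(self, small_lines, tiny_config):
        noisy = add_gbs_noise(small_lines, tiny_config)
        observed = noisy.dosage[~np.isnan(noisy.dosage)]
        assert np.isin(observed, [0.0, 1.0, 2.0]).all()

    def test_invalid_rate_range_rejected(self, small_lines, tiny_config):
        with pytest.raises(ValueError):
            add_gbs_noise(
                small_lines, tiny_config, bad_marker_rate_range=(0.5, 1.0)
            )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"heritability": {"grain_yield": 0.0}},
            {"heritability": {"grain_yield": 1.5}},
            {"het_rate": 1.0},
            {"missing_rate_marker_range": (0.5, 0.2)},
            {"n_markers": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, **kwargs)
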