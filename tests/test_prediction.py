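"""rrBLUP / GBLUP machinery against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from lupings.matrix import GenotypeMatrix
from lupings.prediction import (
    BreedingValueSet,
    adjusted_yield,
    cross_validate,
    fit_rrblup,
    fit_wgblup,
    make_grm,
    predict_gebv,
)
from lupings.simulate import (
    SimulationConfig,
    _scaled_genetic_values,
    simulate_factorial_cross_population,
    simulate_genotype_means,
    simulate_trait_architecture,
)


def random_matrix(n, m, seed=0, maf_low=0.2):
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, 1 - maf_low, m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(float)
    return GenotypeMatrix(
        genotype_ids=[f"g{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        dosage=dosage,
    )


class TestRrblup:
    def test_fixed_lambda_matches_dense_ridge_solve(self):
        """Mixed-model solution equals (W'W + lam I)^-1 W'(y - ybar)."""
        geno = random_matrix(6, 4, seed=1)
        rng = np.random.default_rng(2)
        y = rng.normal(5, 1, 6)
        lam = 3.7
        model = fit_rrblup(geno, y, lam=lam)
        W = geno.dosage - geno.dosage.mean(axis=0)
        oracle = np.linalg.solve(W.T @ W + lam * np.eye(4), W.T @ (y - y.mean()))
        np.testing.assert_allclose(model.marker_effects, oracle, atol=1e-10)
        assert model.intercept == pytest.approx(y.mean())

    def test_constant_phenotype(self):
        geno = random_matrix(8, 5, seed=3)
        model = fit_rrblup(geno, np.full(8, 4.2))
        assert model.intercept == pytest.approx(4.2)
        np.testing.assert_array_equal(model.marker_effects, np.zeros(5))

    def test_noise_free_additive_trait_recovered(self):
        geno = random_matrix(40, 15, seed=4)
        rng = np.random.default_rng(5)
        beta = rng.normal(0, 1, 15)
        W = geno.dosage - geno.dosage.mean(axis=0)
        y = 3.0 + W @ beta
        model = fit_rrblup(geno, y)
        fitted = predict_gebv(model, geno).values.to_numpy()
        assert np.corrcoef(fitted, y)[0, 1] > 0.999

    def test_misaligned_phenotype_rejected(self):
        geno = random_matrix(5, 4)
        with pytest.raises(ValueError):
            fit_rrblup(geno, pd.Series([1.0, 2.0], index=["g0", "nope"]))

    def test_too_few_genotypes_rejected(self):
        geno = random_matrix(2, 4)
        with pytest.raises(ValueError):
            fit_rrblup(geno, np.array([1.0, 2.0]))

    def test_shrinkage_monotone_to_intercept(self):
        """As lambda grows, effects vanish and GEBVs collapse to the mean."""
        geno = random_matrix(20, 10, seed=6)
        y = np.random.default_rng(7).normal(5, 1, 20)
        norms = []
        for lam in (1.0, 1e2, 1e4, 1e8):
            model = fit_rrblup(geno, y, lam=lam)
            norms.append(np.abs(model.marker_effects).max())
        assert norms == sorted(norms, reverse=True)
        big = fit_rrblup(geno, y, lam=1e10)
        gebv = predict_gebv(big, geno).values
        np.testing.assert_allclose(gebv, big.intercept, atol=1e-6)


class TestPredict:
    def test_training_set_reproduces_fitted_values(self):
        geno = random_matrix(12, 6, seed=8)
        y = np.random.default_rng(9).normal(0, 1, 12)
        model = fit_rrblup(geno, y, lam=2.0)
        W = geno.dosage - 2.0 * model.center_freqs
        expected = model.intercept + W @ model.marker_effects
        np.testing.assert_allclose(
            predict_gebv(model, geno).values.to_numpy(), expected
        )

    def test_genotype_at_training_frequencies_predicts_intercept(self):
        # training columns balanced so the allele frequency is exactly 0.5;
        # an all-heterozygous genotype then has a zero centered row
        dosage = np.array([[0, 0, 2], [2, 2, 0], [0, 2, 2], [2, 0, 0]], dtype=float)
        geno = GenotypeMatrix(["a", "b", "c", "d"], ["m1", "m2", "m3"], dosage)
        model = fit_rrblup(geno, np.array([1.0, 2.0, 3.0, 4.0]), lam=1.0)
        new = GenotypeMatrix(["z"], ["m1", "m2", "m3"], np.array([[1.0, 1.0, 1.0]]))
        value = predict_gebv(model, new).values["z"]
        assert value == pytest.approx(model.intercept)

    def test_missing_markers_rejected(self):
        geno = random_matrix(6, 4)
        model = fit_rrblup(geno, np.arange(6.0), lam=1.0)
        new = geno.subset(markers=np.array([0, 1]))
        with pytest.raises(ValueError, match="absent"):
            predict_gebv(model, new)

    def test_independent_set_accuracy_at_n150(self):
        """GEBVs track true genetic values (r > 0.5) with 150 training lines."""
        config = SimulationConfig(
            seed=21, n_markers=300, heritability={"grain_yield": 0.6}
        )
        pop = simulate_factorial_cross_population(config, lines_per_cross=20)
        arch = simulate_trait_architecture(config, "grain_yield")
        gv = _scaled_genetic_values(pop, arch, "grain_yield")
        train = pop.subset(genotypes=np.arange(150))
        test = pop.subset(genotypes=np.arange(150, pop.n_genotypes))
        y = simulate_genotype_means(train, arch, config)
        model = fit_rrblup(train, y)
        pred = predict_gebv(model, test).values.to_numpy()
        assert np.corrcoef(pred, gv[150:])[0, 1] > 0.5


class TestGrm:
    def test_matches_brute_force_double_loop(self):
        geno = random_matrix(5, 8, seed=10)
        G = make_grm(geno).to_numpy()
        p = geno.dosage.mean(axis=0) / 2
        W = geno.dosage - 2 * p
        denom = 2 * np.sum(p * (1 - p))
        oracle = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                oracle[i, j] = np.dot(W[i], W[j]) / denom
        np.testing.assert_allclose(G, oracle, atol=1e-12)

    def test_duplicate_genotypes_identical_rows(self):
        base = random_matrix(4, 6, seed=11)
        dosage = np.vstack([base.dosage, base.dosage[0]])
        geno = GenotypeMatrix(
            [f"g{i}" for i in range(5)], base.marker_ids, dosage
        )
        G = make_grm(geno).to_numpy()
        np.testing.assert_allclose(G[0], G[4])
        np.testing.assert_allclose(G, G.T)

    def test_unit_weights_equal_unweighted(self):
        geno = random_matrix(6, 7, seed=12)
        np.testing.assert_allclose(
            make_grm(geno).to_numpy(),
            make_grm(geno, weights=np.ones(7)).to_numpy(),
        )

    def test_monomorphic_rejected(self):
        geno = GenotypeMatrix(["a", "b"], ["m1"], np.array([[2.0], [2.0]]))
        with pytest.raises(ValueError):
            make_grm(geno)


class TestWgblup:
    def test_unit_weights_equivalent_to_rrblup(self):
        """GBLUP with identity marker weights reproduces rrBLUP GEBVs."""
        geno = random_matrix(30, 40, seed=13)
        y = np.random.default_rng(14).normal(3.5, 0.6, 30)
        rr = fit_rrblup(geno, y)
        wg = fit_wgblup(geno, y, weights=np.ones(40), lam=rr.lam)
        gebv_rr = predict_gebv(rr, geno).values.to_numpy()
        gebv_wg = predict_gebv(wg, geno).values.to_numpy()
        assert np.abs(gebv_wg - gebv_rr).max() < 1e-6 * y.std()

    def test_large_effect_marker_gets_max_weight(self):
        geno = random_matrix(60, 20, seed=15)
        W = geno.dosage - geno.dosage.mean(axis=0)
        y = 5.0 + 2.0 * W[:, 7] + np.random.default_rng(16).normal(0, 0.1, 60)
        wg = fit_wgblup(geno, y)
        assert int(np.argmax(wg.marker_weights)) == 7
        assert wg.marker_weights.mean() == pytest.approx(1.0)

    def test_constant_phenotype(self):
        geno = random_matrix(10, 5, seed=17)
        wg = fit_wgblup(geno, np.full(10, 2.0))
        gebv = predict_gebv(wg, geno).values
        np.testing.assert_allclose(gebv, 2.0)


class TestCrossValidate:
    def test_pure_noise_yields_no_positive_ability(self):
        """On pure noise, predictive ability shows no spurious signal.

        Pooled k-fold r under the null is slightly NEGATIVE by construction
        (held-out predictions shrink to the training-fold mean, which
        anticorrelates with the held-out values), so the calibration check
        is one-sided: across independent null datasets the mean ability must
        not exceed zero by more than sampling noise.
        """
        means = []
        for seed in range(8):
            geno = random_matrix(80, 30, seed=180 + seed)
            y = np.random.default_rng(190 + seed).normal(0, 1, 80)
            means.append(cross_validate(geno, y, k=5, repeats=2, seed=4).mean_r)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert np.mean(means) < 3 * se
        assert np.mean(means) > -0.6  # sanity: not pathologically negative

    def test_noise_free_trait_high_ability(self):
        geno = random_matrix(60, 10, seed=20)
        beta = np.random.default_rng(21).normal(0, 1, 10)
        y = (geno.dosage - geno.dosage.mean(axis=0)) @ beta
        result = cross_validate(geno, y, k=5, repeats=3, seed=0)
        assert result.mean_r > 0.9

    def test_seeded_determinism(self):
        geno = random_matrix(30, 10, seed=22)
        y = np.random.default_rng(23).normal(0, 1, 30)
        a = cross_validate(geno, y, k=5, repeats=2, seed=7)
        b = cross_validate(geno, y, k=5, repeats=2, seed=7)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.r_per_repeat, b.r_per_repeat)

    def test_too_many_folds_rejected(self):
        geno = random_matrix(10, 5)
        with pytest.raises(ValueError, match="k <="):
            cross_validate(geno, np.arange(10.0), k=10)

    def test_ability_grows_with_training_size(self):
        """Mean predictive ability at n=150 exceeds that at n=50."""
        r_small, r_large = [], []
        for seed in range(8):
            config = SimulationConfig(seed=100 + seed, n_markers=200)
            pop = simulate_factorial_cross_population(config, lines_per_cross=10)
            arch = simulate_trait_architecture(config, "grain_yield")
            y = simulate_genotype_means(pop, arch, config)
            sub_small = pop.subset(genotypes=np.arange(50))
            sub_large = pop.subset(genotypes=np.arange(150))
            r_small.append(
                cross_validate(sub_small, y.iloc[:50], k=5, repeats=2, seed=1).mean_r
            )
            r_large.append(
                cross_validate(sub_large, y.iloc[:150], k=5, repeats=2, seed=1).mean_r
            )
        assert np.mean(r_large) > np.mean(r_small)


class TestAdjustedYield:
    def test_uncorrelated_flowering_gives_centered_yield(self):
        flowering = np.array([1.0, 2.0, 3.0, 4.0])
        yields = np.array([5.0, 7.0, 7.0, 5.0])
        # symmetric construction: OLS slope is exactly zero
        adj = adjusted_yield(yields, flowering)
        np.testing.assert_allclose(adj, yields - yields.mean(), atol=1e-12)

    def test_collinear_data_zero_residuals(self):
        flowering = np.array([10.0, 12.0, 15.0, 20.0])
        yields = 2.0 * flowering + 1.0
        np.testing.assert_allclose(adjusted_yield(yields, flowering), 0.0, atol=1e-10)

    def test_five_point_example_matches_normal_equations(self):
        flowering = np.array([10.0, 12.0, 13.0, 15.0, 20.0])
        yields = np.array([3.1, 2.8, 3.6, 2.9, 2.2])
        X = np.column_stack([np.ones(5), flowering])
        beta = np.linalg.solve(X.T @ X, X.T @ yields)
        np.testing.assert_allclose(
            adjusted_yield(yields, flowering), yields - X @ beta, atol=1e-12
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_residuals_orthogonal_to_flowering(self, seed):
        rng = np.random.default_rng(seed)
        flowering = rng.normal(15, 2, 50)
        yields = 3.5 - 0.1 * flowering + rng.normal(0, 0.4, 50)
        adj = adjusted_yield(yields, flowering)
        assert abs(adj.sum()) < 1e-8
        assert abs(np.dot(adj, flowering - flowering.mean())) < 1e-8 * 50

    def test_constant_flowering_warns_and_centers(self):
        yields = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero variance"):
            adj = adjusted_yield(yields, np.full(3, 15.0))
        np.testing.assert_allclose(adj, yields - 2.0)
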