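"""Synthetic cohort generator: determinism, genotype frequencies, factor
recovery, outcome model identifiability and scenario geometry."""

import numpy as np
import pandas as pd
import pytest

from dsgxe.config import SimulationConfig, ConfigurationError
from dsgxe.diffsusc import pa
from dsgxe.phenotypes import pss_total, aggregate_intake_table, SNACK_ITEMS
from dsgxe.ses import standardize_indicators, pca_first_component
from dsgxe.simulate import (
    simulate_genotypes,
    simulate_ses_indicators,
    simulate_covariates,
    simulate_outcomes,
    simulate_analysis_frame,
    simulate_cohort,
    outcome_design,
)


class TestConfig:
    def test_invalid_maf_range(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ConfigurationError):
            SimulationConfig(maf_range=(0.1, 0.6))

    def test_zero_snps_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_snps=0)

    def test_null_scenario_forces_no_interaction(self):
        cfg = SimulationConfig(scenario="null", effect_b3=0.7)
        assert cfg.effect_b3 == 0.0

    def test_unknown_scenario(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(scenario="banana")


class TestGenotypes:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=42, n_subjects=30, n_snps=20)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.snps, b.snps)

    def test_binomial_frequencies_at_half(self):
        cfg = SimulationConfig(
            seed=1, n_subjects=4000, n_snps=3, maf_range=(0.5, 0.5), missing_rate=0.0
        )
        gm = simulate_genotypes(cfg)
        for snp in gm.snp_ids:
            counts = gm.dosages[snp].value_counts(normalize=True)
            assert counts.get(0.0, 0) == pytest.approx(0.25, abs=0.03)
            assert counts.get(1.0, 0) == pytest.approx(0.50, abs=0.03)
            assert counts.get(2.0, 0) == pytest.approx(0.25, abs=0.03)

    def test_missingness_rate(self):
        cfg = SimulationConfig(seed=2, n_subjects=500, n_snps=50, missing_rate=0.1)
        gm = simulate_genotypes(cfg)
        assert gm.dosages.isna().to_numpy().mean() == pytest.approx(0.1, abs=0.01)


class TestSESIndicators:
    def test_loading_recovery_continuous(self):
        cfg = SimulationConfig(seed=7, n_subjects=2000,
                               ses_loadings=(0.8,) * 5)
        table = simulate_ses_indicators(cfg, discretize=False)
        res = pca_first_component(standardize_indicators(table))
        np.testing.assert_allclose(res.loadings, 0.8, atol=0.08)

    def test_near_unit_loading_tracks_latent(self):
        cfg = SimulationConfig(seed=8, n_subjects=500,
                               ses_loadings=(0.9999, 0.7, 0.7, 0.7, 0.7))
        table, latent = simulate_ses_indicators(cfg, discretize=False,
                                                return_latent=True)
        r = np.corrcoef(table["income"], latent)[0, 1]
        assert r > 0.999

    def test_variance_explained_matches_implied_eigenvalue(self):
        cfg = SimulationConfig(seed=9, n_subjects=2000)
        lam = np.array(cfg.ses_loadings)
        implied = np.linalg.eigvalsh(
            np.outer(lam, lam) + np.diag(1 - lam**2)
        ).max() / 5
        table = simulate_ses_indicators(cfg, discretize=False)
        res = pca_first_component(standardize_indicators(table))
        assert res.variance_explained == pytest.approx(implied, abs=0.05)

    def test_discretized_battery_keeps_dominant_factor(self):
        cfg = SimulationConfig(seed=10, n_subjects=2000)
        table = simulate_ses_indicators(cfg, discretize=True)
        assert set(table["public_assistance"].unique()) <= {0.0, 1.0}
        assert table["income"].between(1, 10).all()
        assert table["education"].between(1, 6).all()
        assert table["public_assistance"].mean() == pytest.approx(0.8, abs=0.05)
        res = pca_first_component(standardize_indicators(table))
        assert res.variance_explained > 0.4
        assert (res.loadings > 0.4).all()


class TestOutcomes:
    def _inputs(self, cfg, rng):
        n = cfg.n_subjects
        z = rng.standard_normal(n)
        x = rng.standard_normal(n)
        cov = simulate_covariates(cfg, rng=rng, n=n)
        return z, x, cov

    def test_noiseless_identifiability(self, rng):
        cfg = SimulationConfig(n_subjects=200, seed=1, noise_sd=1e-12)
        z, x, cov = self._inputs(cfg, rng)
        out = simulate_outcomes(cfg, z, x, cov)
        design, coef = outcome_design(cfg, z, x, cov)
        recovered, *_ = np.linalg.lstsq(design.to_numpy(), out["y"].to_numpy(),
                                        rcond=None)
        np.testing.assert_allclose(recovered, coef, atol=1e-8)

    def test_misaligned_inputs_error(self, rng):
        cfg = SimulationConfig(n_subjects=50, seed=1)
        z, x, cov = self._inputs(cfg, rng)
        with pytest.raises(ValueError, match="misaligned"):
            simulate_outcomes(cfg, z[:-1], x, cov)

    def test_ds_scenario_crossover_at_median_gives_pa_half(self):
        values = []
        for seed in range(15):
            cfg = SimulationConfig(n_subjects=500, seed=seed)
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(cfg.n_subjects)
            z = rng.standard_normal(cfg.n_subjects)
            cov = simulate_covariates(cfg, rng=rng, n=cfg.n_subjects)
            _, coef = outcome_design(cfg, z, x, cov)
            xc = -coef[1] / coef[3]
            values.append(pa(x, xc))
        assert np.mean(values) == pytest.approx(0.5, abs=0.05)
        assert all(abs(v - 0.5) <= 0.1 for v in values)

    def test_diathesis_stress_crossover_beyond_2sd(self, rng):
        cfg = SimulationConfig(n_subjects=500, seed=3, scenario="diathesis_stress")
        z, x, cov = self._inputs(cfg, rng)
        _, coef = outcome_design(cfg, z, x, cov)
        xc = -coef[1] / coef[3]
        assert xc >= np.mean(x) + 2 * np.std(x, ddof=1) - 1e-9

    def test_snack_floor_and_pss_bounds(self, rng):
        cfg = SimulationConfig(n_subjects=2000, seed=4, noise_sd=3.0)
        z, x, cov = self._inputs(cfg, rng)
        out = simulate_outcomes(cfg, z, x, cov)
        assert (out["snack_kcal"] >= 0).all()
        assert out["pss_total"].between(0, 40).all()
        assert (out["snack_kcal"] == 0).any()  # the floor actually binds


class TestCohort:
    def test_shapes_and_schema(self):
        cfg = SimulationConfig(seed=5)
        cohort = simulate_cohort(cfg)
        assert len(cohort.phenotypes) == 76
        assert cohort.ses.shape == (76, 5)
        assert not cohort.phenotypes.index.duplicated().any()
        assert cohort.genotypes.dosages.shape == (76, cfg.n_snps)
        assert (cohort.weights["weight"] != 0).any()
        item_cols = [c for c in cohort.phenotypes.columns if c in
                     __import__("dsgxe.phenotypes", fromlist=["FOOD_TABLE"]).FOOD_TABLE]
        assert (cohort.phenotypes[item_cols] >= 0).all().all()

    def test_seed_changes_outcomes_not_schema(self):
        a = simulate_cohort(SimulationConfig(seed=6))
        b = simulate_cohort(SimulationConfig(seed=7))
        assert list(a.phenotypes.columns) == list(b.phenotypes.columns)
        assert not a.phenotypes["pss_item_1"].equals(b.phenotypes["pss_item_1"])

    def test_pss_items_rescore_to_generated_totals(self):
        cohort = simulate_cohort(SimulationConfig(seed=8))
        items = cohort.phenotypes[[f"pss_item_{j}" for j in range(1, 11)]]
        totals, alpha = pss_total(items, reverse_code=True)
        target = np.clip(np.rint(17 + 6 * cohort.truth["y_pss"]), 0, 40)
        np.testing.assert_allclose(totals.to_numpy(), target, atol=0)
        assert 0.5 < alpha <= 1.0

    def test_snack_items_rescore_to_generated_kcal(self):
        cohort = simulate_cohort(SimulationConfig(seed=9))
        scored = aggregate_intake_table(cohort.phenotypes[list(SNACK_ITEMS)])
        target = np.maximum(0.0, 500 + 200 * cohort.truth["y_snack"])
        np.testing.assert_allclose(scored["snack_kcal"], target, rtol=1e-9)

    def test_full_determinism(self):
        a = simulate_cohort(SimulationConfig(seed=10))
        b = simulate_cohort(SimulationConfig(seed=10))
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.ses, b.ses)
        pd.testing.assert_frame_equal(a.weights, b.weights)


class TestAnalysisFrame:
    def test_columns_and_determinism(self):
        cfg = SimulationConfig(n_subjects=150, seed=11)
        a = simulate_analysis_frame(cfg)
        b = simulate_analysis_frame(cfg)
        pd.testing.assert_frame_equal(a, b)
        for col in ("pred_expr", "ses_composite", "age", "sex", "bmi_z",
                    "pc1", "pc2", "y", "snack_kcal", "pss_total"):
            assert col in a.columns
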