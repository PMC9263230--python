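"""Synthetic-data generator: marginals, LD, trait construction, GWAS oracle."""

import numpy as np
import pytest

from eqtlmr import (SimScenario, align_alleles, compute_summary_stats,
                    empirical_ld, inject_outliers, simulate_genotypes,
                    simulate_summary_pair, simulate_traits)
from conftest import make_set


class TestGenotypes:
    def test_mean_dosage_matches_hardy_weinberg(self):
        scn = SimScenario(n_exposure_cohort=50_000, n_outcome_cohort=100,
                          n_variants=4, maf=[0.5, 0.5, 0.5, 0.5], seed=1)
        g = simulate_genotypes(scn, "exposure")
        assert np.all(np.abs(g.mean(axis=0) - 1.0) < 0.02)
        assert set(np.unique(g)) <= {0.0, 1.0, 2.0}

    def test_zero_ld_decay_gives_independent_variants(self):
        scn = SimScenario(n_exposure_cohort=50_000, n_outcome_cohort=100,
                          n_variants=6, maf=[0.3] * 6, ld_decay=0.0, seed=2)
        g = simulate_genotypes(scn, "exposure")
        r = np.corrcoef(g, rowvar=False)
        off = np.abs(r[np.triu_indices(6, 1)])
        assert off.mean() < 0.02

    def test_ld_decays_with_distance(self):
        scn = SimScenario(n_exposure_cohort=50_000, n_outcome_cohort=100,
                          n_variants=5, maf=[0.3] * 5, ld_decay=0.6, seed=3)
        g = simulate_genotypes(scn, "exposure")
        r = np.corrcoef(g, rowvar=False)
        assert r[0, 1] > r[0, 2] > r[0, 4] > 0

    def test_deterministic_given_seed_and_cohort(self, small_scenario):
        a = simulate_genotypes(small_scenario, "exposure")
        b = simulate_genotypes(small_scenario, "exposure")
        c = simulate_genotypes(small_scenario, "outcome")
        assert np.array_equal(a, b)
        assert not np.array_equal(a[: len(c)], c)

    def test_maf_length_mismatch_fatal(self):
        with pytest.raises(ValueError, match="maf"):
            SimScenario(n_variants=3, maf=[0.1, 0.2])


class TestTraits:
    def test_null_causal_effect_decorrelates_score_and_outcome(self):
        scn = SimScenario(n_exposure_cohort=100, n_outcome_cohort=50_000,
                          causal_effect=0.0, seed=4)
        g = simulate_genotypes(scn, "outcome")
        ph = simulate_traits(g, scn, cohort="outcome")
        score = (g - g.mean(0)) @ ph.attrs["true_weights"]
        assert abs(np.corrcoef(score, ph["ldl"])[0, 1]) < 0.02

    def test_liability_prevalence_hit(self):
        scn = SimScenario(n_exposure_cohort=100, n_outcome_cohort=50_000,
                          liability_prevalence=0.06, seed=5)
        g = simulate_genotypes(scn, "outcome")
        ph = simulate_traits(g, scn, cohort="outcome")
        assert ph["ckd"].mean() == pytest.approx(0.06, abs=0.005)

    def test_expression_variance_explained_on_target(self):
        from eqtlmr import individual_level_r2

        scn = SimScenario(n_exposure_cohort=30_000, n_outcome_cohort=100, seed=6)
        g = simulate_genotypes(scn, "exposure")
        ph = simulate_traits(g, scn, cohort="exposure")
        r2 = individual_level_r2(g, ph["expression"].to_numpy())
        assert r2 == pytest.approx(0.015, abs=0.004)

    def test_acr_left_censoring_at_detection_limit(self):
        scn = SimScenario(n_exposure_cohort=100, n_outcome_cohort=20_000, seed=7)
        g = simulate_genotypes(scn, "outcome")
        ph = simulate_traits(g, scn, cohort="outcome", acr_detection_limit=0.3)
        floor = np.log(0.3)
        assert ph["log_acr"].min() == pytest.approx(floor)
        assert np.isclose(ph["log_acr"], floor).mean() > 0.05

    def test_phenotype_table_columns(self, small_scenario):
        g = simulate_genotypes(small_scenario, "outcome")
        ph = simulate_traits(g, small_scenario, cohort="outcome")
        for col in ("sample_id", "expression", "ldl", "log_egfr", "log_acr",
                    "ckd", "age", "sex", "pc1", "pc20"):
            assert col in ph.columns
        assert set(ph["ckd"].unique()) <= {0, 1}


class TestSummaryStats:
    def test_exact_fit_degenerate(self):
        g = np.array([[0, 1, 2, 0, 1, 2]], dtype=float).T
        recs = compute_summary_stats(g, 2.0 * g[:, 0], "linear")
        assert recs[0].beta == pytest.approx(2.0)
        assert recs[0].se == 0.0 and recs[0].pvalue is None

    def test_all_zero_trait_gives_zero_betas(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(50, 4)).astype(float)
        recs = compute_summary_stats(g, np.zeros(50), "linear")
        assert all(r.beta == pytest.approx(0.0) for r in recs)

    def test_linear_estimator_consistency(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=(20_000, 1)).astype(float)
        y = 0.3 * g[:, 0] + rng.normal(0, 1, 20_000)
        rec = compute_summary_stats(g, y, "linear")[0]
        assert abs(rec.beta - 0.3) < 3 * rec.se
        assert rec.eaf == pytest.approx(0.3, abs=0.01)

    def test_logistic_estimator_consistency(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, size=(8000, 1)).astype(float)
        logit = -2.0 + 0.4 * g[:, 0]
        y = rng.random(8000) < 1 / (1 + np.exp(-logit))
        rec = compute_summary_stats(g, y.astype(float), "logistic")[0]
        assert abs(rec.beta - 0.4) < 3 * rec.se

    def test_monomorphic_variant_emitted_without_estimate(self):
        g = np.column_stack([np.ones(30), np.tile([0, 1, 2], 10)])
        recs = compute_summary_stats(g, np.random.default_rng(3).normal(size=30),
                                     "linear")
        assert recs[0].beta is None and recs[0].se is None
        assert recs[1].beta is not None

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.4, size=(500, 3)).astype(float)
        y = g @ [0.2, -0.1, 0.0] + rng.normal(0, 1, 500)
        recs = compute_summary_stats(g, y, "linear")
        for j, rec in enumerate(recs):
            fit = sm.OLS(y, sm.add_constant(g[:, j])).fit()
            assert rec.beta == pytest.approx(fit.params[1], rel=1e-10)
            assert rec.se == pytest.approx(fit.bse[1], rel=1e-10)
            assert rec.pvalue == pytest.approx(fit.pvalues[1], rel=1e-8)


class TestTwoSampleStructure:
    def test_cohort_summary_stats_uncorrelated_under_null(self):
        # disjoint cohorts: per-variant betas from the two studies share no
        # sampling noise, so their cross-correlation is centred on zero
        corrs = []
        for s in range(60):
            scn = SimScenario(n_exposure_cohort=2000, n_outcome_cohort=2000,
                              causal_effect=0.0, seed=s)
            ex, oc = simulate_summary_pair(scn)
            corrs.append(np.corrcoef([r.beta for r in ex],
                                     [r.beta for r in oc])[0, 1])
        assert abs(np.mean(corrs)) < 0.1

    def test_empirical_ld_diagonal_and_range(self, small_scenario):
        g = simulate_genotypes(small_scenario, "exposure")
        ld = empirical_ld(g, small_scenario.variant_ids())
        assert np.allclose(np.diag(ld.r2), 1.0)
        assert ld.r2.min() >= 0 and ld.r2.max() <= 1


class TestInjectOutliers:
    def _hset(self):
        rng = np.random.default_rng(10)
        bx = rng.uniform(0.03, 0.08, 10)
        by = 0.2 * bx + rng.normal(0, 0.01, 10)
        return make_set(bx, by, [0.01] * 10)

    def test_zero_count_is_identity(self):
        hs = self._hset()
        out, idx = inject_outliers(hs, 0, 5.0, seed=1)
        assert idx == []
        assert [p.beta_outcome for p in out.pairs] == \
               [p.beta_outcome for p in hs.pairs]

    def test_same_seed_same_indices(self):
        hs = self._hset()
        _, i1 = inject_outliers(hs, 3, 1.0, seed=5)
        _, i2 = inject_outliers(hs, 3, 1.0, seed=5)
        assert i1 == i2

    def test_count_at_least_k_fatal(self):
        with pytest.raises(ValueError):
            inject_outliers(self._hset(), 10, 1.0, seed=1)

    def test_input_not_mutated(self):
        hs = self._hset()
        before = [p.beta_outcome for p in hs.pairs]
        inject_outliers(hs, 2, 9.9, seed=2)
        assert [p.beta_outcome for p in hs.pairs] == before

    def test_perturbed_variant_most_outlying(self, default_study):
        # at 10x the median outcome SE the perturbed variant has the most
        # extreme precision-standardized ratio in nearly every seed
        _, hs = default_study
        mag = 10 * np.median([p.se_outcome for p in hs.pairs])
        hits = 0
        for s in range(100):
            pert, idx = inject_outliers(hs, 1, mag, seed=s)
            bx, _, by, sy = pert.arrays()
            z = np.abs(by / bx - np.median(by / bx)) / (sy / np.abs(bx))
            hits += int(np.argmax(z) == idx[0])
        assert hits >= 95
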