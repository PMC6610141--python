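"""Generator properties: determinism, allele frequencies, DAG structure,
two-sample summary statistics, selection."""

import dataclasses

import numpy as np
import pytest

import edumr
from edumr import SelectionModel, SimParams, apply_selection, simulate_cohort
from edumr.simulate import sample_summary_from_truth, simulate_two_sample_summary


class TestSimParams:
    def test_both_mediation_paths_rejected(self):
        with pytest.raises(ValueError, match="alternatives"):
            SimParams(alpha_E=0.3, alpha_CA=0.3)

    def test_maf_range_bounds(self):
        with pytest.raises(ValueError, match="maf_range"):
            SimParams(maf_range=(0.001, 0.4))


class TestCohortGeneration:
    def test_determinism(self, small_params):
        a, pa = simulate_cohort(small_params)
        b, pb = simulate_cohort(small_params)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(a.edu_years, b.edu_years)
        np.testing.assert_array_equal(a.smoke_ever, b.smoke_ever)
        np.testing.assert_array_equal(pa.weight_edu, pb.weight_edu)

    def test_seed_changes_output(self, small_params):
        a, _ = simulate_cohort(small_params)
        b, _ = simulate_cohort(dataclasses.replace(small_params, seed=43))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_outcome_logic(self, small_cohort):
        cohort, _ = small_cohort
        assert not np.any((cohort.smoke_current == 1) & (cohort.smoke_ever == 0))
        ever = cohort.smoke_ever == 1
        assert np.isnan(cohort.smoke_former[~ever]).all()
        former = cohort.smoke_former[ever]
        np.testing.assert_array_equal(
            former == 1, cohort.smoke_current[ever] == 0
        )

    def test_allele_frequency_recovery(self, small_cohort, small_params):
        cohort, panel = small_cohort
        maf_hat = cohort.dosages.mean(axis=0) / 2
        se = np.sqrt(panel.maf * (1 - panel.maf) / (2 * small_params.n_individuals))
        z = np.abs(maf_hat - panel.maf) / se
        assert np.mean(z <= 3) >= 0.95

    def test_null_association(self):
        """With all structural effects off, education and smoking are
        independent."""
        p = SimParams(
            n_individuals=20_000, n_snps_edu=10, n_snps_cog=5,
            beta1=0.0, beta2=0.0, alpha_CA=0.0,
            cessation_beta1=0.0, cessation_beta2=0.0,
            confounder_effects=(0.0, 0.0, 0.0), seed=5,
        )
        cohort, _ = simulate_cohort(p)
        y = cohort.smoke_current.astype(float)
        x = cohort.edu_years
        slope = np.cov(x, y)[0, 1] / np.var(x)
        mc_se = np.std(y) / (np.std(x) * np.sqrt(p.n_individuals))
        assert abs(slope) < 3 * mc_se

    def test_mediation_coefficient_recovery(self):
        """Cognition->education path: OLS of education on cognition (the
        generating equation) recovers alpha_CA."""
        p = SimParams(
            n_individuals=50_000, n_snps_edu=10, n_snps_cog=5,
            alpha_E=0.0, alpha_CA=0.5, confounder_effects=(0.0, 0.0, 0.0),
            seed=17,
        )
        cohort, _ = simulate_cohort(p)
        slope = (
            np.cov(cohort.cog_score, cohort.edu_years)[0, 1]
            / np.var(cohort.cog_score)
        )
        mc_se = np.std(cohort.edu_years) / (
            np.std(cohort.cog_score) * np.sqrt(p.n_individuals)
        )
        assert abs(slope - 0.5) < 3 * mc_se

    def test_prevalence_emulation(self):
        """Defaults reproduce the target cohort's smoking prevalences."""
        cohort, _ = simulate_cohort(SimParams(n_individuals=60_000, seed=2))
        assert abs(cohort.smoke_ever.mean() - 0.438) < 0.02
        assert abs(cohort.smoke_current.mean() - 0.077) < 0.015
        assert abs(np.nanmean(cohort.smoke_former) - 0.824) < 0.02

    def test_clamp_warning(self):
        p = SimParams(
            n_individuals=5000, n_snps_edu=10, n_snps_cog=5,
            beta1=-0.2, alpha_CA=0.0, baseline_prevalence=0.2, seed=1,
        )
        with pytest.warns(UserWarning, match="clamped"):
            simulate_cohort(p)

    def test_dynastic_variant_transmits_parental_alleles(self):
        p = SimParams(
            n_individuals=30_000, n_snps_edu=10, n_snps_cog=5,
            alpha_CA=0.0, dynastic_effect=0.02, seed=8,
        )
        cohort, panel = simulate_cohort(p)
        # inherited dosages still match the generating MAFs
        maf_hat = cohort.dosages.mean(axis=0) / 2
        se = np.sqrt(panel.maf * (1 - panel.maf) / (2 * p.n_individuals))
        assert np.mean(np.abs(maf_hat - panel.maf) / se <= 3) >= 0.9
        # a nonzero dynastic path inflates the score-outcome association
        # relative to the no-dynastic generator with identical draws
        p0 = dataclasses.replace(p, dynastic_effect=0.0)
        cohort0, panel0 = simulate_cohort(p0)
        s1 = edumr.compute_prs(cohort.dosages, panel, "edu")
        s0 = edumr.compute_prs(cohort0.dosages, panel0, "edu")
        a1 = np.cov(s1, cohort.smoke_ever.astype(float))[0, 1]
        a0 = np.cov(s0, cohort0.smoke_ever.astype(float))[0, 1]
        assert abs(a1) > abs(a0)


class TestTwoSampleSummary:
    def test_wald_ratio_consistency(self):
        """One strong SNP affecting only education, beta1=0.1: the ratio
        Gamma/pi recovers 0.1 within 2 delta-method SEs."""
        p = SimParams(
            n_individuals=1000, n_snps_edu=1, n_snps_cog=1,
            beta1=0.1, beta2=0.0, alpha_CA=0.0,
            confounder_effects=(0.0, 0.0, 0.0),
            r2_edu=0.05, baseline_prevalence=0.5, seed=3,
        )
        data = simulate_two_sample_summary(p, 40_000, 40_000, outcome="ever")
        j = int(np.argmax(np.abs(data.pi1)))
        ratio, se = edumr.wald_ratio(
            data.gamma[j], data.se_gamma[j], data.pi1[j], data.se_pi1[j]
        )
        assert abs(ratio - 0.1) < 2 * se

    def test_null_test_size(self):
        """All effects zero: about 5% of SNP-outcome z-scores exceed 1.96."""
        p = SimParams(
            n_individuals=1000, n_snps_edu=60, n_snps_cog=40,
            beta1=0.0, beta2=0.0, alpha_CA=0.0,
            confounder_effects=(0.0, 0.0, 0.0), seed=9,
        )
        data = simulate_two_sample_summary(p, 5000, 5000, outcome="ever")
        frac = np.mean(np.abs(data.gamma / data.se_gamma) > 1.96)
        # binomial band around 0.05 with L=100
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / data.n_snps)

    def test_se_scales_with_sqrt_n(self):
        p = SimParams(
            n_individuals=1000, n_snps_edu=10, n_snps_cog=5,
            alpha_CA=0.0, seed=4,
        )
        d_small = simulate_two_sample_summary(p, 5000, 5000)
        d_big = simulate_two_sample_summary(p, 20_000, 5000)
        ratio = np.median(d_small.se_pi1 / d_big.se_pi1)
        assert abs(ratio - 2.0) < 0.15  # sqrt(20000/5000) = 2

    def test_determinism(self, small_params):
        a = simulate_two_sample_summary(small_params, 2000, 2000)
        b = simulate_two_sample_summary(small_params, 2000, 2000)
        np.testing.assert_array_equal(a.gamma, b.gamma)

    def test_log_odds_scale_matches_statsmodels(self):
        import statsmodels.api as sm

        p = SimParams(
            n_individuals=1000, n_snps_edu=3, n_snps_cog=2,
            alpha_CA=0.0, seed=6,
        )
        data = simulate_two_sample_summary(p, 2000, 3000, scale="log_odds")
        # refit one SNP's logistic regression independently, reusing the
        # shared instrument panel of the two-sample design
        seeds = np.random.default_rng(p.seed).integers(0, 2**31 - 1, 3)
        _, panel = simulate_cohort(
            dataclasses.replace(p, n_individuals=2000, seed=int(seeds[0]))
        )
        cohort, _ = simulate_cohort(
            dataclasses.replace(p, n_individuals=3000, seed=int(seeds[2])),
            panel=panel,
        )
        g = cohort.dosages[:, 0].astype(float)
        y = cohort.smoke_ever.astype(float)
        fit = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
        np.testing.assert_allclose(data.gamma[0], fit.params[1], atol=1e-6)
        np.testing.assert_allclose(data.se_gamma[0], fit.bse[1], rtol=1e-3)


class TestSelection:
    def test_uniform_selection_probabilities(self, small_cohort, small_params):
        cohort, _ = small_cohort
        p = dataclasses.replace(
            small_params, selection_model=SelectionModel(intercept=0.4)
        )
        selected, prob = apply_selection(cohort, p)
        assert np.allclose(prob, prob[0])
        assert 0 < selected.n < cohort.n

    def test_education_selection_is_monotone(self, small_cohort, small_params):
        cohort, _ = small_cohort
        p = dataclasses.replace(
            small_params, selection_model=SelectionModel(coef_edu=0.5)
        )
        selected, _ = apply_selection(cohort, p)
        assert selected.edu_years.mean() > cohort.edu_years.mean()

    def test_collider_bias_from_joint_selection(self):
        """Selecting on education and smoking jointly distorts the naive
        education-smoking association (collider bias)."""
        base = SimParams(
            n_individuals=100_000, n_snps_edu=10, n_snps_cog=5,
            beta1=0.0, beta2=0.0, alpha_CA=0.0,
            confounder_effects=(0.0, 0.0, 0.0), seed=13,
        )
        cohort, _ = simulate_cohort(base)
        p = dataclasses.replace(
            base,
            selection_model=SelectionModel(
                intercept=0.0, coef_edu=0.6, coef_smoke=-1.5
            ),
        )
        selected, _ = apply_selection(cohort, p)

        def slope(c):
            y = c.smoke_current.astype(float)
            return np.cov(c.edu_years, y)[0, 1] / np.var(c.edu_years)

        full, sel = slope(cohort), slope(selected)
        mc_se = 0.3 / (2.4 * np.sqrt(selected.n))
        assert abs(sel - full) > 3 * mc_se

    def test_empty_selection_errors(self, small_cohort, small_params):
        cohort, _ = small_cohort
        p = dataclasses.replace(
            small_params, selection_model=SelectionModel(intercept=-40.0)
        )
        with pytest.raises(ValueError, match="every individual"):
            apply_selection(cohort, p)


class TestParametricSummarySampler:
    def test_truth_embedding(self):
        d = sample_summary_from_truth(50, -0.09, 0.12, se_gamma=1e-8, se_pi=1e-12, seed=0)
        np.testing.assert_allclose(d.gamma, -0.09 * d.pi1 + 0.12 * d.pi2, atol=1e-6)
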