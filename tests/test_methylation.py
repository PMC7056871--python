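"""Covariate ledger, mixed-model fitting and EWAS behaviour."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import binomial_99ci
from miromics.methylation import (
    BASE_COVARIATES,
    covariates_for_trait,
    fit_cpg_trait_model,
    run_ewas,
)


class TestCovariateLedger:
    def test_wc_adds_bmi(self):
        spec = covariates_for_trait("WC")
        assert set(spec.fixed) == set(BASE_COVARIATES) | {"bmi"}

    def test_bmi_never_adjusts_for_itself(self):
        assert set(covariates_for_trait("BMI").fixed) == set(BASE_COVARIATES)

    def test_lipid_traits_add_bmi_and_lipid_medication(self):
        spec = covariates_for_trait("HDL")
        assert set(spec.fixed) == set(BASE_COVARIATES) | {"bmi", "lipid_medication"}

    def test_glycemic_and_cardiovascular_additions(self):
        assert "diabetic_medication" in covariates_for_trait("FG").fixed
        dbp = set(covariates_for_trait("DBP").fixed)
        assert {"bmi", "bp_medication", "lipid_medication"} <= dbp

    def test_random_effect_is_batch(self):
        assert covariates_for_trait("TC").random == ("batch",)

    def test_expression_base_drops_cell_counts(self):
        spec = covariates_for_trait("TC", cell_counts=False)
        assert set(spec.fixed) == {"age", "sex", "current_smoking",
                                   "bmi", "lipid_medication"}

    def test_unknown_trait_raises(self):
        with pytest.raises(KeyError):
            covariates_for_trait("HEIGHT")


def simulate_probe(rng, n=700, slope=0.01, batch_sd=0.01, resid_sd=0.02,
                   n_batches=8):
    trait = pd.Series(rng.standard_normal(n) * 10 + 100, name="TG")
    batch = pd.Series(rng.integers(0, n_batches, n))
    offsets = rng.normal(0, batch_sd, n_batches)
    probe = pd.Series(
        0.5 + slope * (trait - trait.mean())
        + offsets[batch.to_numpy()] + rng.normal(0, resid_sd, n)
    )
    return probe, trait, batch


class TestMixedModelFit:
    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(3)
        probe, trait, batch = simulate_probe(rng, slope=0.01)
        fit = fit_cpg_trait_model(probe, trait, pd.DataFrame(index=probe.index),
                                  batch)
        assert abs(fit.beta - 0.01) < 3 * fit.se

    def test_single_batch_matches_plain_ols(self):
        rng = np.random.default_rng(4)
        n = 200
        trait = pd.Series(rng.standard_normal(n))
        probe = pd.Series(0.4 + 0.02 * trait + rng.normal(0, 0.02, n))
        batch = pd.Series(["b0"] * n)
        fit = fit_cpg_trait_model(probe, trait, pd.DataFrame(index=probe.index),
                                  batch)
        X = sm.add_constant(pd.DataFrame({"x": trait}))
        ols = sm.OLS(probe, X).fit()
        assert fit.beta == pytest.approx(float(ols.params["x"]), rel=1e-6)
        assert fit.used_fallback

    def test_degenerate_inputs_raise(self):
        n = 100
        rng = np.random.default_rng(5)
        const = pd.Series(np.full(n, 0.5))
        trait = pd.Series(rng.standard_normal(n))
        batch = pd.Series(rng.integers(0, 4, n))
        empty_cov = pd.DataFrame(index=const.index)
        with pytest.raises(ValueError, match="degenerate"):
            fit_cpg_trait_model(const, trait, empty_cov, batch)
        with pytest.raises(ValueError, match="degenerate"):
            fit_cpg_trait_model(trait, const, empty_cov, batch)
        with pytest.raises(ValueError, match="complete cases"):
            fit_cpg_trait_model(trait[:10], trait[:10], empty_cov, batch[:10])

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(6)
        n = 120
        trait = pd.Series(rng.standard_normal(n))
        probe = pd.Series(0.5 + rng.normal(0, 0.02, n))
        cov = pd.DataFrame({"a": rng.standard_normal(n)})
        cov["b"] = 2 * cov["a"]
        with pytest.raises(ValueError, match="collinear"):
            fit_cpg_trait_model(probe, trait, cov,
                                pd.Series(rng.integers(0, 4, n)))

    def test_estimator_bias_below_five_percent(self):
        """Mean recovered coefficient over 200 simulations within 5% of
        the planted value."""
        rng = np.random.default_rng(8)
        estimates = []
        for _ in range(200):
            probe, trait, batch = simulate_probe(rng, n=200, slope=0.01,
                                                 n_batches=5)
            fit = fit_cpg_trait_model(probe, trait,
                                      pd.DataFrame(index=probe.index), batch)
            estimates.append(fit.beta)
        assert abs(np.mean(estimates) - 0.01) < 0.05 * 0.01 + 3 * np.std(estimates) / np.sqrt(200)
        assert abs(np.mean(estimates) / 0.01 - 1) < 0.05


class TestNullCalibration:
    def test_type_one_error_at_nominal_level(self, ewas_null_pvalues):
        frac = float((ewas_null_pvalues < 0.05).mean())
        lo, hi = binomial_99ci(0.05, len(ewas_null_pvalues))
        assert lo <= frac <= hi, frac

    def test_null_pvalues_roughly_uniform(self, ewas_null_pvalues):
        # coarse uniformity: deciles each within +-50% of expectation
        hist, _ = np.histogram(ewas_null_pvalues, bins=10, range=(0, 1))
        assert hist.min() > 0.5 * len(ewas_null_pvalues) / 10
        assert hist.max() < 1.5 * len(ewas_null_pvalues) / 10


class TestRunEwas:
    def _phenotypes(self, cohort):
        return cohort.meth_phenotypes

    def test_zero_candidates_empty_table(self, small_cohort):
        out, log = run_ewas(small_cohort.methylation,
                            small_cohort.meth_phenotypes, [], ["TC"])
        assert out.empty and log.n_fits == 0

    def test_no_shared_samples_hard_error(self, small_cohort):
        pheno = small_cohort.meth_phenotypes.copy()
        pheno.index = ["x" + s for s in pheno.index]
        with pytest.raises(ValueError, match="overlapping"):
            run_ewas(small_cohort.methylation, pheno,
                     [small_cohort.methylation.index[0]], ["TC"])

    def test_beta_value_range_enforced(self, small_cohort):
        bad = small_cohort.methylation.copy()
        bad.iloc[0, 0] = 1.5
        with pytest.raises(ValueError, match="beta-values"):
            run_ewas(bad, small_cohort.meth_phenotypes,
                     [bad.index[0]], ["TC"])

    def test_planted_cpg_effects_detected(self, small_cohort):
        """Planted CpG-trait effects (2x residual SD) are recovered at the
        nominal level."""
        truth = small_cohort.truth["cpg"]
        probes = list(truth["probe_id"])
        out, _ = run_ewas(small_cohort.methylation,
                          small_cohort.meth_phenotypes, probes,
                          sorted(truth["trait"].unique()))
        hits = out.merge(truth, left_on=["feature_id", "trait"],
                         right_on=["probe_id", "trait"])
        assert (hits["significant"].mean()) >= 0.9
        assert len(hits) == len(truth)

    def test_deterministic_given_fixed_inputs(self, small_cohort):
        probes = list(small_cohort.methylation.index[:3])
        a, _ = run_ewas(small_cohort.methylation,
                        small_cohort.meth_phenotypes, probes, ["TC"])
        b, _ = run_ewas(small_cohort.methylation,
                        small_cohort.meth_phenotypes, probes, ["TC"])
        pd.testing.assert_frame_equal(a, b)
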