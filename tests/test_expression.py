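"""CPM normalization, LLOQ derivation, expression filters and associations."""

import numpy as np
import pandas as pd
import pytest

from conftest import binomial_99ci
from miromics.annotation import GenomicInterval, SiteRecord
from miromics.expression import (
    antitonic_fit,
    cpm_log2,
    fit_lloq,
    normalize_counts,
    target_gene_lookup,
    well_expressed,
)
from miromics.expression import test_expression_association as expr_assoc
from miromics.fixtures import expression_layer_results


def counts_frame(arr, prefix="miR"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}-{i}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])],
    )


class TestCpmLog2:
    def test_whole_library_single_mirna(self):
        out = cpm_log2(counts_frame([[5]]))
        assert out.iloc[0, 0] == pytest.approx(np.log2(1e6 + 1), abs=1e-9)

    def test_zero_count_maps_to_zero(self):
        out = cpm_log2(counts_frame([[0], [10]]))
        assert out.iloc[0, 0] == 0.0

    def test_cpm_columns_conserve_one_million(self):
        rng = np.random.default_rng(9)
        counts = counts_frame(rng.integers(0, 500, size=(50, 20)))
        log2cpm = cpm_log2(counts)
        cpm = np.exp2(log2cpm.to_numpy()) - 1
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_library_size_invariance(self):
        rng = np.random.default_rng(10)
        counts = counts_frame(rng.integers(1, 100, size=(30, 4)))
        scaled = counts.copy()
        scaled["S0"] = counts["S0"] * 7
        a, b = cpm_log2(counts), cpm_log2(scaled)
        pd.testing.assert_series_equal(a["S0"], b["S0"])

    def test_all_zero_sample_rejected_by_name(self):
        counts = counts_frame([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="S1"):
            cpm_log2(counts)


class TestLloq:
    GEN_A, GEN_B, GEN_C = 2.0, 3.0, 0.2  # sd = A*exp(-mean/B) + C

    def _generate(self, rng, n=500, noise=0.05):
        means = rng.uniform(0.0, 10.0, n)
        sds = self.GEN_A * np.exp(-means / self.GEN_B) + self.GEN_C
        return means, sds + rng.normal(0, noise, n)

    def test_recovers_analytic_crossing(self):
        rng = np.random.default_rng(11)
        means, sds = self._generate(rng)
        lloq = fit_lloq(means, sds)
        # the default cut is the midpoint of the curve's range over the
        # observed means; invert the generating curve at that midpoint
        lo = self.GEN_A * np.exp(-means.max() / self.GEN_B) + self.GEN_C
        hi = self.GEN_A * np.exp(-means.min() / self.GEN_B) + self.GEN_C
        c = (lo + hi) / 2
        analytic = -self.GEN_B * np.log((c - self.GEN_C) / self.GEN_A)
        assert abs(lloq - analytic) <= 0.25

    def test_noiseless_decreasing_input_reproduced_exactly(self):
        x = np.linspace(0, 8, 40)
        y = 5.0 - 0.5 * x
        xs, fit = antitonic_fit(x, y, smooth_window=1)
        assert np.allclose(fit, 5.0 - 0.5 * xs)

    def test_antitonic_fit_non_increasing_and_sort_invariant(self):
        rng = np.random.default_rng(12)
        means, sds = self._generate(rng, n=200)
        xs, fit = antitonic_fit(means, sds)
        assert np.all(np.diff(fit) <= 1e-12)
        perm = rng.permutation(len(means))
        xs2, fit2 = antitonic_fit(means[perm], sds[perm])
        assert np.allclose(xs, xs2) and np.allclose(fit, fit2)

    def test_flat_profile_degenerate_branch(self):
        means = np.linspace(1, 5, 20)
        sds = np.full(20, 0.3)
        assert fit_lloq(means, sds) == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_lloq(np.arange(5.0), np.arange(5.0))


class TestWellExpressed:
    def test_always_above_kept_and_exact_half_excluded(self):
        log2cpm = pd.DataFrame(
            {"S0": [5.0, 5.0], "S1": [5.0, 1.0], "S2": [5.0, 5.0],
             "S3": [5.0, 1.0]},
            index=["always", "half"],
        )
        kept = well_expressed(log2cpm, lloq=3.0)
        assert kept == {"always"}  # exactly 50% above is excluded (strict)

    def test_planted_high_expressers_recovered(self):
        rng = np.random.default_rng(13)
        high = rng.normal(8.0, 0.5, size=(60, 40))
        low = rng.normal(1.0, 0.5, size=(140, 40))
        log2cpm = counts_frame(np.vstack([high, low]))
        kept = well_expressed(log2cpm, lloq=4.0)
        assert kept == {f"miR-{i}" for i in range(60)}

    def test_monotone_in_lloq(self):
        rng = np.random.default_rng(14)
        log2cpm = counts_frame(rng.normal(4, 2, size=(80, 30)))
        sets = [well_expressed(log2cpm, q) for q in (2.0, 4.0, 6.0)]
        assert sets[2] <= sets[1] <= sets[0]

    def test_normalize_counts_pipeline(self, small_cohort):
        info = normalize_counts(small_cohort.counts)
        planted = set(small_cohort.truth["mirna"]["mature"])
        assert planted <= info.well_expressed
        # mean-SD profile the LLOQ stage assumes: decreasing in the mean
        xs, fit = antitonic_fit(info.means.to_numpy(), info.sds.to_numpy())
        assert np.all(np.diff(fit) <= 1e-12)


class TestAssociations:
    def test_published_hits_pass_nominal_filter(self):
        df = expression_layer_results()
        row = df[(df.feature_id == "miR-10b-5p") & (df.trait == "TC")].iloc[0]
        assert row.beta == pytest.approx(0.352) and row.p == pytest.approx(3.30e-11)
        assert bool(row.significant)

    def test_linear_recovery_in_cohort(self, small_cohort):
        from miromics.expression import run_expression_associations

        info = normalize_counts(small_cohort.counts)
        truth = small_cohort.truth["expression"]
        out = run_expression_associations(
            info.log2cpm, small_cohort.expr_phenotypes,
            sorted(truth["mature"].unique()), sorted(truth["trait"].unique()),
        )
        hits = out.merge(truth, left_on=["feature_id", "trait"],
                         right_on=["mature", "trait"])
        assert len(hits) == len(truth)
        assert hits["significant"].all()

    def test_permutation_null_calibrated(self, expression_null_pvalues):
        frac = float((expression_null_pvalues < 0.05).mean())
        lo, hi = binomial_99ci(0.05, len(expression_null_pvalues))
        assert lo <= frac <= hi, frac

    def test_logistic_recovery(self):
        # planted log-OR 0.5 at prevalence 0.15, n=1000
        rng = np.random.default_rng(15)
        n = 1_000
        x = pd.Series(rng.standard_normal(n), name="miR-x")
        lin = np.log(0.15 / 0.85) + 0.5 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        pheno = pd.DataFrame({
            "T2D": y,
            "age": rng.normal(65, 8, n),
            "sex": rng.integers(0, 2, n),
            "current_smoking": (rng.random(n) < 0.2).astype(int),
            "bmi": rng.normal(27, 4, n),
            "diabetic_medication": (rng.random(n) < 0.1).astype(int),
        })
        res = expr_assoc(x, "T2D", pheno)
        assert abs(res["beta"] - 0.5) < 3 * res["se"]

    def test_logistic_separation_flagged(self):
        n = 60
        x = pd.Series(np.r_[np.ones(30), -np.ones(30)], name="miR-sep")
        pheno = pd.DataFrame({
            "T2D": np.r_[np.ones(30), np.zeros(30)].astype(int),
            "age": np.linspace(50, 80, n),
            "sex": ([0, 1] * 30)[:n],
            "current_smoking": 0,
            "bmi": 27.0,
            "diabetic_medication": 0,
        })
        res = expr_assoc(x, "T2D", pheno)
        assert res["separation"] and np.isnan(res["p"])


class TestTargetGeneLookup:
    def _sumstats(self, rsids, p):
        return pd.DataFrame({
            "rsid": rsids, "trait": "TC", "effect_allele": "A",
            "other_allele": "G", "beta": 0.1, "se": 0.02, "p": p,
            "n": 5_000, "panel": "hapmap",
        })

    def test_empty_gene_set(self):
        out = target_gene_lookup([], {}, [], self._sumstats([], []))
        assert out.empty

    def test_per_mirna_threshold_is_alpha_over_snps(self):
        genes = [("GENE1", GenomicInterval("1", 1_000, 2_000))]
        sites = [SiteRecord(site_id=f"rs{i}", site_kind="snp", chrom="1",
                            pos=1_100 + i) for i in range(10)]
        ss = self._sumstats([f"rs{i}" for i in range(10)],
                            [1e-4] + [0.5] * 9)
        out = target_gene_lookup(genes, {"GENE1": ["mir-a"]}, sites, ss)
        assert np.allclose(out["threshold"], 0.05 / 10)
        sig = out[out["significant"]]
        assert list(sig["feature_id"]) == ["rs0"]  # 1e-4 < 5e-3
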