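"""Bonferroni thresholds, LD pruning and summary-statistic candidate tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from miromics.fixtures import top_snp_table
from miromics.gwas import (
    LdMatrix,
    bonferroni_threshold,
    empirical_r2,
    ld_prune,
    summarize_by_mirna,
    validate_sumstats,
)
from miromics.gwas import test_gwas_associations as gwas_lookup


def sumstat_row(rsid, trait, beta, se=None, p=None, panel="hapmap",
                ea="A", oa="G"):
    if p is None:
        p = 2 * stats.norm.sf(abs(beta / se))
    return {"rsid": rsid, "trait": trait, "effect_allele": ea,
            "other_allele": oa, "beta": beta, "se": se, "p": p,
            "n": 5_000, "panel": panel}


class TestBonferroni:
    def test_published_denominators(self):
        assert bonferroni_threshold(0.05, 2_358) == pytest.approx(2.12e-5, rel=5e-3)
        assert bonferroni_threshold(0.05, 8_652) == pytest.approx(5.78e-6, rel=5e-3)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_monotone_in_m_linear_in_alpha(self):
        ms = [1, 2, 10, 100, 10_000]
        ts = [bonferroni_threshold(0.05, m) for m in ms]
        assert all(a > b for a, b in zip(ts, ts[1:]))
        assert bonferroni_threshold(0.02, 7) == pytest.approx(
            0.4 * bonferroni_threshold(0.05, 7)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)


def brute_force_check(kept, ld, r2_max, positions, window_bp):
    """No surviving pair closer than half a window may exceed r2_max."""
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            if abs(positions[a] - positions[b]) <= window_bp // 2:
                assert ld.value(a, b) <= r2_max, (a, b, ld.value(a, b))


class TestLdPrune:
    def test_single_snp_kept(self):
        ld = LdMatrix(["rs1"], np.ones((1, 1)))
        assert ld_prune(["rs1"], ld) == ["rs1"]

    def test_three_snp_worked_example(self):
        # r2(1,2)=0.9 forces dropping the later member of the worst pair
        r2 = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        ld = LdMatrix(["rs1", "rs2", "rs3"], r2)
        assert ld_prune(["rs1", "rs2", "rs3"], ld, r2_max=0.7) == ["rs1", "rs3"]

    def test_complete_dependence_keeps_one(self):
        n = 6
        ld = LdMatrix([f"rs{i}" for i in range(n)], np.ones((n, n)))
        assert ld_prune([f"rs{i}" for i in range(n)], ld, r2_max=0.7) == ["rs0"]

    def test_bruteforce_and_idempotence_on_genotype_ld(self, small_cohort):
        rsids = list(small_cohort.genotypes.columns[:120])
        geno = small_cohort.genotypes[rsids].to_numpy()
        ld = empirical_r2(geno, rsids)
        positions = dict(zip(small_cohort.snp_positions["rsid"],
                             small_cohort.snp_positions["pos"]))
        kept = ld_prune(rsids, ld, r2_max=0.7, window_bp=250_000,
                        positions=positions)
        assert 0 < len(kept) < len(rsids)
        brute_force_check(kept, ld, 0.7, positions, 250_000)
        again = ld_prune(kept, ld, r2_max=0.7, window_bp=250_000,
                         positions=positions)
        assert again == kept  # pruning its own output is a no-op

    def test_output_preserves_input_order(self):
        r2 = np.eye(4)
        names = ["rsD", "rsB", "rsC", "rsA"]
        ld = LdMatrix(names, r2)
        assert ld_prune(names, ld) == names

    def test_ld_matrix_validation(self):
        with pytest.raises(ValueError):
            LdMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            LdMatrix(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestAssociations:
    def test_empty_sumstats(self):
        ann = pd.DataFrame({"site_id": ["rs1"], "mirna_id": ["mir-a"]})
        out = gwas_lookup(ann, pd.DataFrame(
            columns=["rsid", "trait", "effect_allele", "other_allele",
                     "beta", "se", "p", "n", "panel"]), {"hapmap": 1e-5})
        assert out.empty

    def test_planted_effect_flagged(self):
        # beta 0.4, se 0.05 -> two-sided normal Wald p ~ 1.3e-15
        ann = pd.DataFrame({"site_id": ["rs1"], "mirna_id": ["mir-a"]})
        ss = pd.DataFrame([sumstat_row("rs1", "TC", 0.4, se=0.05)])
        out = gwas_lookup(ann, ss, {"hapmap": 2.12e-5})
        assert out.loc[0, "p"] == pytest.approx(1.3e-15, rel=0.05)
        assert bool(out.loc[0, "significant"])

    def test_published_locus_significant_at_1000g_threshold(self):
        row = top_snp_table().query("rsid == 'rs4722551'").iloc[0]
        ann = pd.DataFrame({"site_id": [row.rsid], "mirna_id": [row.mirna]})
        ss = pd.DataFrame([sumstat_row(row.rsid, row.trait, row.beta,
                                       p=row.p, panel="1000g")])
        out = gwas_lookup(
            ann, ss, {"1000g": bonferroni_threshold(0.05, 8_652)}
        )
        assert bool(out.loc[0, "significant"])

    def test_duplicate_rows_raise(self):
        ss = pd.DataFrame([sumstat_row("rs1", "TC", 0.1, se=0.1)] * 2)
        with pytest.raises(ValueError, match="rs1"):
            validate_sumstats(ss)

    def test_allele_flip_changes_sign_and_ambiguous_dropped(self):
        ann = pd.DataFrame(
            {"site_id": ["rs1", "rs2"], "mirna_id": ["mir-a", "mir-b"],
             "a1": ["A", "A"], "a2": ["G", "T"]}
        )
        ss = pd.DataFrame([
            sumstat_row("rs1", "TC", 0.3, se=0.05, ea="G", oa="A"),  # flipped
            sumstat_row("rs2", "TC", 0.3, se=0.05, ea="T", oa="A"),  # ambiguous
        ])
        out = gwas_lookup(ann, ss, {"hapmap": 1e-5})
        assert list(out["feature_id"]) == ["rs1"]
        assert out.loc[0, "beta"] == pytest.approx(-0.3)

    def test_untested_snps_are_absent_not_failed(self):
        ann = pd.DataFrame({"site_id": ["rs1", "rs9"],
                            "mirna_id": ["mir-a", "mir-b"]})
        ss = pd.DataFrame([sumstat_row("rs1", "TC", 0.0, se=0.1)])
        out = gwas_lookup(ann, ss, {"hapmap": 1e-5})
        assert set(out["feature_id"]) == {"rs1"}


class TestLocusSummary:
    def _results(self, rows):
        df = pd.DataFrame(rows)
        df["layer"] = "snp"
        return df

    def test_minimum_p_represents_locus(self):
        res = self._results([
            {"feature_id": "rs1", "mirna_ids": ["mir-a"], "trait": "TC",
             "beta": 0.1, "se": 0.01, "p": 1e-8, "n": 100, "pos": 10,
             "threshold": 1e-5, "significant": True},
            {"feature_id": "rs2", "mirna_ids": ["mir-a"], "trait": "TC",
             "beta": 0.1, "se": 0.01, "p": 1e-6, "n": 100, "pos": 20,
             "threshold": 1e-5, "significant": True},
        ])
        top = summarize_by_mirna(res)
        assert len(top) == 1 and top.loc[0, "p"] == 1e-8

    def test_multi_mirna_snp_appears_under_both(self):
        res = self._results([
            {"feature_id": "rs1", "mirna_ids": ["mir-a", "mir-b"],
             "trait": "TC", "beta": 0.1, "se": 0.01, "p": 1e-8, "n": 100,
             "pos": 10, "threshold": 1e-5, "significant": True},
        ])
        top = summarize_by_mirna(res)
        assert set(top["mirna_id"]) == {"mir-a", "mir-b"}

    def test_published_table_locus_count(self):
        t2 = top_snp_table()
        res = self._results([
            {"feature_id": r.rsid, "mirna_ids": [r.mirna], "trait": r.trait,
             "beta": r.beta, "se": np.nan, "p": r.p, "n": np.nan,
             "pos": r.pos, "threshold": 5.78e-6, "significant": True}
            for r in t2.itertuples(index=False)
        ])
        top = summarize_by_mirna(res)
        # 20 printed locus rows (two list a pair of miRNAs -> 22 entries)
        assert len(top[["feature_id", "trait"]].drop_duplicates()) == 20
        assert len(top) == 22


class TestTypeIError:
    def test_null_gwas_false_positive_rate(self, null_cohort):
        """Under the null generator the flagged fraction at level t matches
        t within the binomial 99% CI (on LD-pruned, hence independent, SNPs)."""
        from conftest import binomial_99ci

        ss = null_cohort.sumstats
        positions = dict(zip(null_cohort.snp_positions["rsid"],
                             null_cohort.snp_positions["pos"]))
        rsids = list(null_cohort.genotypes.columns)
        ld = empirical_r2(null_cohort.genotypes.to_numpy(), rsids)
        kept = set(ld_prune(rsids, ld, r2_max=0.7, positions=positions))
        pvals = ss.loc[(ss["trait"] == "TC") & ss["rsid"].isin(kept), "p"]
        frac = float((pvals < 0.05).mean())
        lo, hi = binomial_99ci(0.05, len(pvals))
        assert lo <= frac <= hi, (frac, len(pvals))
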