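"""End-to-end orchestration of the multi-omics association pipeline.

Chains the stages in study order: region annotation -> catalog union ->
per-panel LD pruning and Bonferroni thresholds -> GWAS candidate lookup ->
candidate-based EWAS -> expression normalization/filtering/association ->
me-QTL / eQTM cross-referencing -> three-layer integration. Operates on a
:class:`~miromics.simulate.SyntheticCohort` (or any object exposing the
same fields read from files).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import annotation as ann
from . import expression as expr
from . import gwas
from . import integration as integ
from . import methylation as meth
from . import qtl
from .traits import BINARY_TRAITS

GWAS_ALPHA = 0.05


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline run."""

    snp_annotations: pd.DataFrame
    cpg_annotations: pd.DataFrame
    merged_catalog_size: int
    pruned_counts: dict[str, int]
    thresholds: dict[str, float]
    snp_results: pd.DataFrame
    locus_summary: pd.DataFrame
    ewas_results: pd.DataFrame
    ewas_log: object
    normalization: object
    expr_results: pd.DataFrame
    meqtl_crossref: pd.DataFrame
    eqtm_crossref: pd.DataFrame
    evidence: object
    records: list = field(default_factory=list)
    report: dict = field(default_factory=dict)


def annotate_cohort(cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(SNP annotation frame, CpG annotation frame), both long format with
    eQTL-catalog SNPs mapped to precursor ids."""
    regions = ann.build_mirna_regions(cohort.mirna_records, cohort.config.flank_bp)
    snp_ann = ann.map_sites_to_regions(cohort.snp_catalog, regions)
    cpg_ann = ann.map_sites_to_regions(cohort.cpg_manifest, regions)
    eqtl_ann = ann.annotate_eqtl_sites(cohort.eqtl_catalog)
    mature_map = cohort.mature_to_mirna
    for a in eqtl_ann:
        a.mirna_ids = sorted({mature_map.get(m, m) for m in a.mirna_ids})
    snp_frame = pd.concat(
        [ann.annotations_to_frame(snp_ann), ann.annotations_to_frame(eqtl_ann)],
        ignore_index=True,
    ).drop_duplicates(subset=["site_id", "mirna_id"], keep="first")
    return snp_frame, ann.annotations_to_frame(cpg_ann)


def panel_thresholds(
    cohort, snp_frame: pd.DataFrame, alpha: float = GWAS_ALPHA,
    r2_max: float = 0.7, window_bp: int = 250_000,
) -> tuple[dict[str, float], dict[str, int]]:
    """Per-panel Bonferroni thresholds from LD-pruned independent-SNP counts.

    The pruned count is computed on the candidate SNPs present in each
    panel's GWAS, using empirical r2 from the genotype matrix."""
    candidate = set(snp_frame["site_id"])
    positions = dict(
        zip(cohort.snp_positions["rsid"], cohort.snp_positions["pos"])
    )
    thresholds: dict[str, float] = {}
    counts: dict[str, int] = {}
    for panel, sub in cohort.sumstats.groupby("panel"):
        rsids = [
            r for r in cohort.genotypes.columns
            if r in candidate and r in set(sub["rsid"])
        ]
        if not rsids:
            continue
        ld = gwas.empirical_r2(cohort.genotypes[rsids].to_numpy(), rsids)
        kept = gwas.ld_prune(rsids, ld, r2_max=r2_max, window_bp=window_bp,
                             positions=positions)
        counts[panel] = len(kept)
        thresholds[panel] = gwas.bonferroni_threshold(alpha, len(kept))
    return thresholds, counts


def run_pipeline(
    cohort,
    ewas_traits: list[str] | None = None,
    expr_traits: list[str] | None = None,
    outdir=None,
) -> PipelineResult:
    """Run every stage on a cohort; optionally write the integration report."""
    cfg = cohort.config
    snp_frame, cpg_frame = annotate_cohort(cohort)
    merged = ann.merge_snp_catalogs(cohort.snp_catalog, cohort.eqtl_catalog)

    thresholds, pruned_counts = panel_thresholds(cohort, snp_frame)
    snp_results = gwas.test_gwas_associations(snp_frame, cohort.sumstats,
                                              thresholds)
    locus_summary = gwas.summarize_by_mirna(snp_results)

    # candidate-based downstream layers: only miRNAs hit at the SNP layer
    hit_mirnas = set(locus_summary["mirna_id"])
    candidate_probes = sorted(
        cpg_frame.loc[cpg_frame["mirna_id"].isin(hit_mirnas), "site_id"].unique()
    )
    traits_meth = ewas_traits or [t for t in cfg.traits if t not in BINARY_TRAITS]
    ewas_results, ewas_log = meth.run_ewas(
        cohort.methylation, cohort.meth_phenotypes, candidate_probes,
        traits_meth,
    )

    norm = expr.normalize_counts(cohort.counts, housekeeping=cohort.housekeeping)
    mature_map = cohort.mature_to_mirna
    candidate_mature = sorted(
        m for m in norm.well_expressed if mature_map.get(m, m) in hit_mirnas
    )
    traits_expr = expr_traits or [
        t for t in list(cfg.traits) + list(cfg.prevalence)
        if t in cohort.expr_phenotypes.columns
    ]
    expr_results = expr.run_expression_associations(
        norm.log2cpm, cohort.expr_phenotypes, candidate_mature, traits_expr
    )

    meqtl_x = qtl.crossref_meqtl(snp_results, cohort.meqtl, ewas_results)
    eqtm_x = qtl.crossref_eqtm(ewas_results, cohort.eqtm)

    evidence = integ.build_evidence_matrix(
        snp_results,
        cpg_results=ewas_results,
        expr_results=expr_results,
        eqtm_crossref=eqtm_x,
        flags=cohort.flags,
        cpg_to_mirna=cpg_frame.rename(columns={"site_id": "site_id"}),
        mature_to_mirna=mature_map,
        known_mirnas={r.mirna_id for r in cohort.mirna_records},
    )
    records = integ.select_multiomics(evidence)
    records = integ.prioritize(records, evidence)
    report = {}
    if outdir is not None:
        report = integ.write_report(
            records, evidence, outdir,
            metadata={"seed": cfg.seed, "n_mirnas": cfg.n_mirnas},
        )

    return PipelineResult(
        snp_annotations=snp_frame,
        cpg_annotations=cpg_frame,
        merged_catalog_size=len(merged),
        pruned_counts=pruned_counts,
        thresholds=thresholds,
        snp_results=snp_results,
        locus_summary=locus_summary,
        ewas_results=ewas_results,
        ewas_log=ewas_log,
        normalization=norm,
        expr_results=expr_results,
        meqtl_crossref=meqtl_x,
        eqtm_crossref=eqtm_x,
        evidence=evidence,
        records=records,
        report=report,
    )
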