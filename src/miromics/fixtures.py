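"""Published worked-example tables and catalog-cardinality fixtures.

The association tables printed by the source study (top SNP hits, me-QTL
pairs, expression hits, integrated miRNAs) are embedded verbatim and exposed
both as DataFrames and as TSV writers, so the lookup, cross-referencing and
integration stages can be exercised on real published values. Catalog
fixtures reproduce the published candidate-SNP cardinalities (18,545
region-scan SNPs, 5,528 miR-eQTL SNPs, 83 shared) with synthetic rsIDs.

me-QTL FDR values are not printed in the study; the fixture stores a
synthetic placeholder (0.04) consistent with the FDR < 0.05 retention rule.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation import SiteRecord

# --- top SNP associations (rsid, chrom, pos, effect/other allele, gene,
#     context, trait, beta, p), one row per locus-leading SNP, 20 miRNAs.
TOP_SNP_ROWS = [
    ("miR-6886-3p", "rs17248720", "19", 11198187, "C", "T", "LDLR", "intronic", "LDL", 0.226, 2.40e-148),
    ("miR-6863", "rs13306673", "16", 56900931, "C", "T", "SLC12A3", "intronic", "HDL", 0.098, 2.76e-48),
    ("miR-4263", "rs2305929", "2", 28113911, "G", "A", "BRE", "intronic", "TG", 0.064, 1.13e-44),
    ("miR-6773", "rs8057119", "16", 68268836, "T", "C", "ESRP2", "intronic", "HDL", 0.072, 5.21e-40),
    ("miR-611", "rs174538", "11", 61560081, "G", "A", "THEM258", "exonic", "LDL", 0.050, 1.07e-34),
    ("miR-1908-5p", "rs174548", "11", 61571348, "C", "G", "FADS1", "exonic", "LDL", 0.047, 2.29e-31),
    ("miR-10b-5p", "rs532436", "9", 136149830, "A", "G", "ABO", "exonic", "LDL", 0.079, 4.02e-30),
    ("miR-126-5p", "rs532436", "9", 136149830, "A", "G", "ABO", "intronic", "LDL", 0.079, 4.02e-30),
    ("miR-4721", "rs4788099", "16", 28763228, "G", "A", "TUMF", "exonic", "BMI", 0.031, 1.09e-24),
    ("miR-4531", "rs6509170", "19", 45159636, "C", "A", "LOC107985305", "intronic", "LDL", 0.127, 1.54e-22),
    ("miR-199a-1", "rs11085748", "19", 10927540, "T", "C", "DNM2", "intronic", "LDL", 0.055, 1.46e-19),
    ("miR-4999", "rs7254882", "19", 8359822, "C", "T", "MIR4999", "intergenic", "HDL", 0.033, 6.66e-18),
    ("miR-4639", "rs3757354", "6", 16127407, "C", "T", "MYLIP", "intronic", "LDL", 0.038, 2.09e-17),
    ("miR-640", "rs1000237", "19", 19518316, "T", "A", "GATAD2A", "intronic", "TG", 0.033, 1.61e-16),
    ("miR-3161", "rs79837139", "11", 48000780, "C", "T", "PTPRJ", "intronic", "HDL", 0.062, 2.99e-16),
    ("miR-100-5p", "rs7117842", "11", 122663796, "C", "T", "UBASH3B", "intergenic", "TC", 0.029, 2.48e-15),
    ("miR-125b-5p", "rs7117842", "11", 122663796, "C", "T", "UBASH3B", "intergenic", "TC", 0.029, 2.48e-15),
    ("miR-148a-3p", "rs4722551", "7", 25991826, "C", "T", "MIR148A", "intergenic", "LDL", 0.039, 3.95e-14),
    ("miR-139", "rs11605042", "11", 72700619, "A", "G", "ARAP1", "intronic", "Pro-Ins", -0.053, 5.24e-13),
    ("miR-3941", "rs71486610", "10", 124134803, "C", "G", "PLEKHA1", "intronic", "T2D", -0.081, 3.30e-11),
    ("miR-6745", "rs901750", "11", 47209472, "A", "G", "PACSIN3", "intronic", "HDL", 0.024, 3.95e-11),
    ("miR-196a-2-3p", "rs11614913", "12", 53991815, "C", "T", "MIR196A2", "intergenic", "WHR", 0.029, 6.90e-11),
]

#: the two slashed entries in the printed table list two miRNAs for one SNP;
#: rows above expand them, so the table covers 20 printed miRNA entries.
N_TOP_SNP_MIRNA_ENTRIES = 20

# --- me-QTL pairs with cardiometabolic-associated CpGs: 8 SNP-CpG pairs,
#     7 unique cis SNPs (one SNP drives two CpGs).
MEQTL_ROWS = [
    ("miR-611", "rs174538", "cg16150798", "cis", False, "FG;LDL;HDL;TG;TC", "WC"),
    ("miR-588", "rs9388486", "cg20229609", "cis", False, "T2D", "SBP;DBP"),
    ("miR-1908-5p", "rs174548", "cg03921599", "cis", True, "FG;HbA1c;LDL;HDL;TG;TC", "LDL;TC"),
    ("miR-199a-1", "rs3786719", "cg02907064", "cis", False, "LDL;TC", "LDL"),
    ("miR-6745", "rs901750", "cg00724111", "cis", False, "HDL", "FI;SBP;DBP"),
    ("miR-8073", "rs3809346", "cg22382805", "cis", False, "CAD", "FI"),
    ("miR-653;miR-489", "rs2528521", "cg06934092", "cis", False, "BMI", "FG;FI;TC"),
    ("miR-8073", "rs3809346", "cg19700260", "cis", False, "CAD", "DBP"),
]

# --- plasma expression associations: 12 rows (mature miRNA, beta, p, trait).
EXPRESSION_ROWS = [
    ("miR-126-3p", 0.379, 1.09e-14, "TC"),
    ("miR-10b-5p", 0.352, 3.30e-11, "TC"),
    ("miR-126-5p", 0.258, 3.75e-11, "TC"),
    ("miR-148a-3p", 0.189, 8.01e-06, "TC"),
    ("miR-199a-1-3p", 0.171, 3.38e-05, "TC"),
    ("miR-125b-5p", 0.159, 2.43e-03, "TC"),
    ("miR-100-5p", 0.141, 3.15e-03, "TC"),
    ("miR-6886-3p", -0.083, 9.49e-03, "TC"),
    ("miR-126-5p", -0.365, 1.24e-02, "CHD"),
    ("miR-4681", -0.440, 2.13e-02, "WC"),
    ("miR-199a-1-5p", 0.074, 3.38e-02, "TC"),
    ("miR-126-3p", -0.385, 3.54e-02, "CHD"),
]

# --- integrated multi-omics miRNAs: SNP trait sets, best SNP, the
#     functional-eQTL flag, the matching CpG/expression evidence.
INTEGRATED_ROWS = [
    ("miR-10b-5p", "LDL;TC;CAD;T2D", "rs532436", 4.02e-30, True, "cg25820279", 4.37e-02, "TC", "", "", 3.30e-11, "TC"),
    ("miR-148a-3p", "LDL;TC;TG", "rs4722551", 3.95e-14, True, "cg18188200", 1.94e-03, "TC", "", "", 8.01e-06, "TC"),
    ("miR-125b-5p", "TC;LDL;HDL", "rs7117842", 2.48e-15, True, "cg06749053", 2.39e-02, "LDL", "cg26363555", "HDL", 2.43e-03, "TC"),
    ("miR-100-5p", "TC;LDL;HDL", "rs7117842", 2.48e-15, True, "cg14724899", 4.02e-02, "HDL", "", "", 3.15e-03, "TC"),
    ("miR-6886-3p", "LDL;TC;CAD", "rs17248720", 2.40e-148, False, "cg19751789", 8.03e-04, "TC", "", "", 9.49e-03, "TC"),
]

#: mature-form ids used in the expression table mapped onto the SNP-layer
#: miRNA id scheme.
MATURE_TO_MIRNA = {
    "miR-199a-1-3p": "miR-199a-1",
    "miR-199a-1-5p": "miR-199a-1",
    "miR-126-3p": "miR-126-5p",
}

#: extra trait-associated CpGs reported in the EWAS narrative.
EXTRA_CPG_ROWS = [
    ("cg15616915", "miR-26b", "TG", 0.009, 1.59e-04),
    ("cg03722243", "miR-489", "BMI", 0.001, 1.55e-03),
    ("cg03722243", "miR-653", "BMI", 0.001, 1.55e-03),
    ("cg26363555", "miR-125b-5p", "FG", 0.012, 1.0e-03),
    ("cg26363555", "miR-125b-5p", "DBP", 2.0e-04, 1.0e-03),
    ("cg26363555", "miR-125b-5p", "HDL", -0.004, 1.0e-03),
    ("cg03891346", "miR-100-5p", "WC", 5.0e-04, 1.0e-03),
]

#: miR-eQTM reference pairs (retained at FDR < 0.01).
EQTM_ROWS = [
    ("cg26363555", "miR-125b-5p", -1, 1e-03),
    ("cg26363555", "miR-100-5p", -1, 1e-03),
    ("cg03891346", "miR-100-5p", -1, 1e-03),
]

CATALOG_SIZES = {"region_scan": 18_545, "eqtl_catalog": 5_528, "overlap": 83}


def top_snp_table() -> pd.DataFrame:
    return pd.DataFrame(
        TOP_SNP_ROWS,
        columns=["mirna", "rsid", "chrom", "pos", "effect_allele",
                 "other_allele", "gene", "context", "trait", "beta", "p"],
    )


def meqtl_table() -> pd.DataFrame:
    df = pd.DataFrame(
        MEQTL_ROWS,
        columns=["mirna", "rsid", "cpg", "cis_trans", "mir_eqtl",
                 "snp_traits", "cpg_traits"],
    )
    df["fdr"] = 0.04  # synthetic placeholder under the FDR < 0.05 rule
    return df


def expression_table() -> pd.DataFrame:
    return pd.DataFrame(EXPRESSION_ROWS, columns=["mirna", "beta", "p", "trait"])


def integrated_table() -> pd.DataFrame:
    return pd.DataFrame(
        INTEGRATED_ROWS,
        columns=["mirna", "snp_traits", "rsid", "snp_p", "eqtl_evidence",
                 "cpg", "cpg_p", "cpg_trait", "eqtm_cpg", "eqtm_trait",
                 "expr_p", "expr_trait"],
    )


def eqtm_table() -> pd.DataFrame:
    return pd.DataFrame(EQTM_ROWS, columns=["cpg", "mirna", "direction", "fdr"])


# ---------------------------------------------------------------------------
# Layer views for the integration stage


def snp_layer_results() -> pd.DataFrame:
    """SNP-layer AssociationResult rows: the integrated table's full trait
    sets plus the remaining top-SNP loci (single printed trait each)."""
    integrated = {r[0] for r in INTEGRATED_ROWS}
    rows = []
    for mirna, traits, rsid, p, *_ in INTEGRATED_ROWS:
        for trait in traits.split(";"):
            rows.append({"feature_id": rsid, "mirna_ids": [mirna],
                         "trait": trait, "layer": "snp", "p": p,
                         "significant": True})
    for mirna, rsid, _c, _pos, _a, _b, _g, _ctx, trait, _beta, p in TOP_SNP_ROWS:
        if mirna in integrated:
            continue
        rows.append({"feature_id": rsid, "mirna_ids": [mirna],
                     "trait": trait, "layer": "snp", "p": p,
                     "significant": True})
    return pd.DataFrame(rows)


def cpg_layer_results() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(EWAS AssociationResult rows, CpG -> miRNA mapping)."""
    rows, mapping = [], []
    for mirna, _traits, _rsid, _p, _flag, cpg, cpg_p, cpg_trait, *_ in INTEGRATED_ROWS:
        rows.append({"feature_id": cpg, "trait": cpg_trait, "layer": "cpg",
                     "p": cpg_p, "significant": cpg_p < 0.05})
        mapping.append({"site_id": cpg, "mirna_id": mirna})
    for cpg, mirna, trait, beta, p in EXTRA_CPG_ROWS:
        rows.append({"feature_id": cpg, "trait": trait, "layer": "cpg",
                     "beta": beta, "p": p, "significant": p < 0.05})
        mapping.append({"site_id": cpg, "mirna_id": mirna})
    return pd.DataFrame(rows), pd.DataFrame(mapping).drop_duplicates()


def expression_layer_results(alpha: float = 0.05) -> pd.DataFrame:
    """Expression AssociationResult rows with the nominal filter applied."""
    df = expression_table().rename(columns={"mirna": "feature_id"})
    df["layer"] = "expression"
    df["threshold"] = alpha
    df["significant"] = df["p"] < alpha
    return df


def prioritization_flags() -> pd.DataFrame:
    """Functional-evidence flags per miRNA (the eQTL column of the
    integrated table)."""
    return pd.DataFrame(
        [
            {"mirna": mirna, "eqtl_evidence": flag,
             "tissue_expression": flag, "structure_change": False}
            for mirna, _t, _r, _p, flag, *_ in INTEGRATED_ROWS
        ]
    )


def published_meqtl_inputs() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(snp results, me-QTL pairs, cpg results) reproducing the published
    me-QTL cross-reference: 8 pairs, 7 unique cis SNPs."""
    t3 = meqtl_table()
    snp_rows, cpg_rows = [], []
    for r in t3.itertuples(index=False):
        mirnas = r.mirna.split(";")
        for trait in r.snp_traits.split(";"):
            snp_rows.append({"feature_id": r.rsid, "mirna_ids": mirnas,
                             "trait": trait, "layer": "snp",
                             "p": 1e-8, "significant": True})
        for trait in r.cpg_traits.split(";"):
            cpg_rows.append({"feature_id": r.cpg, "trait": trait,
                             "layer": "cpg", "p": 1e-3, "significant": True})
    snp = pd.DataFrame(snp_rows).drop_duplicates(subset=["feature_id", "trait"])
    cpg = pd.DataFrame(cpg_rows).drop_duplicates(subset=["feature_id", "trait"])
    return snp, t3[["rsid", "cpg", "cis_trans", "fdr"]], cpg


# ---------------------------------------------------------------------------
# Catalog-cardinality fixtures


def catalog_fixtures() -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Synthetic rsID catalogs with the published cardinalities:
    |region| = 18,545, |eqtl| = 5,528, overlap = 83."""
    n_region = CATALOG_SIZES["region_scan"]
    n_eqtl = CATALOG_SIZES["eqtl_catalog"]
    n_shared = CATALOG_SIZES["overlap"]

    def snp(i: int, source: str) -> SiteRecord:
        return SiteRecord(
            site_id=f"rs{i:07d}", site_kind="snp", chrom="1", pos=i,
            sources=frozenset({source}),
        )

    region = [snp(i, "region_scan") for i in range(1, n_region + 1)]
    shared = [snp(i, "eqtl_catalog") for i in range(1, n_shared + 1)]
    private = [
        snp(i, "eqtl_catalog")
        for i in range(1_000_000, 1_000_000 + n_eqtl - n_shared)
    ]
    return region, shared + private


# ---------------------------------------------------------------------------
# Demo annotation fixture

#: A plausible precursor window for the miR-148a locus on chromosome 7.
#: The study does not print the precursor coordinates it used; this fixture
#: places the precursor so that the published flank SNP rs4722551
#: (chr7:25,991,826) falls inside the +/-2 kb window.
DEMO_GFF3 = """\
##gff-version 3
7\t.\tmiRNA_primary_transcript\t25989933\t25990000\t.\t-\t.\tID=MI0000253;Name=hsa-mir-148a
7\t.\tmiRNA\t25989940\t25989961\t.\t-\t.\tID=MIMAT0000243;Name=hsa-miR-148a-3p;Derives_from=MI0000253
11\t.\tmiRNA_primary_transcript\t121970465\t121970552\t.\t-\t.\tID=MI0000446;Name=hsa-mir-100
11\t.\tmiRNA\t121970527\t121970548\t.\t-\t.\tID=MIMAT0000098;Name=hsa-miR-100-5p;Derives_from=MI0000446
"""


def write_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write every fixture as TSV/GFF3 files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tables = {
        "top_snps.tsv": top_snp_table(),
        "meqtl_pairs.tsv": meqtl_table(),
        "expression_hits.tsv": expression_table(),
        "integrated_mirnas.tsv": integrated_table(),
        "eqtm_pairs.tsv": eqtm_table(),
        "flags.tsv": prioritization_flags(),
    }
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    region, eqtl = catalog_fixtures()
    for name, catalog in (("catalog_region.tsv", region), ("catalog_eqtl.tsv", eqtl)):
        path = outdir / name
        pd.DataFrame(
            [{"rsid": s.site_id, "chrom": s.chrom, "pos": s.pos,
              "a1": "", "a2": "", "source": sorted(s.sources)[0]}
             for s in catalog]
        ).to_csv(path, sep="\t", index=False)
        paths[name] = path
    gff = outdir / "mirna_demo.gff3"
    gff.write_text(DEMO_GFF3)
    paths["mirna_demo.gff3"] = gff
    return paths


make_fixtures = write_fixtures
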