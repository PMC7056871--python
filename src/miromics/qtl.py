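"""me-QTL and miR-eQTM cross-referencing.

External reference tables — SNP->CpG methylation effects (me-QTLs) and
CpG->miRNA expression effects (miR-eQTMs) — are joined against the
pipeline's trait-associated SNPs and CpGs. A me-QTL is *cis* when SNP and
CpG lie on the same chromosome no further than 250 kb apart (boundary
inclusive), *trans* otherwise. Reference FDR values are trusted as
reported, not recomputed; eQTM pairs are pre-filtered at FDR < 0.01.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CIS_WINDOW_BP = 250_000
EQTM_FDR_MAX = 0.01


def classify_cis_trans(
    snp_chrom: str, snp_pos: int, cpg_chrom: str, cpg_pos: int,
    window_bp: int = CIS_WINDOW_BP,
) -> str:
    """``cis`` iff same chromosome and |snp - cpg| <= window (else ``trans``)."""
    for label in (snp_chrom, cpg_chrom):
        if not label or pd.isna(label):
            raise ValueError("unknown chromosome in cis/trans classification")
    if snp_chrom != cpg_chrom:
        return "trans"
    return "cis" if abs(int(snp_pos) - int(cpg_pos)) <= window_bp else "trans"


def read_meqtl_table(path: str | Path) -> pd.DataFrame:
    """Read ``meqtl.tsv``: rsid, snp_chr, snp_pos, cpg, cpg_chr, cpg_pos, fdr
    (optionally a pre-assigned cis_trans column, re-derived when positions
    are present)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_chr": str, "cpg_chr": str})
    if {"snp_chr", "snp_pos", "cpg_chr", "cpg_pos"} <= set(df.columns):
        df["cis_trans"] = [
            classify_cis_trans(r.snp_chr, r.snp_pos, r.cpg_chr, r.cpg_pos)
            for r in df.itertuples(index=False)
        ]
    elif "cis_trans" not in df.columns:
        raise ValueError("meqtl table needs positions or a cis_trans column")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("me-QTL FDR values must lie in [0, 1]")
    return df


def read_eqtm_table(path: str | Path, fdr_max: float = EQTM_FDR_MAX) -> pd.DataFrame:
    """Read ``eqtm.tsv`` (cpg, mirna, direction, fdr) keeping FDR < fdr_max."""
    df = pd.read_csv(path, sep="\t")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("eQTM FDR values must lie in [0, 1]")
    return df[df["fdr"] < fdr_max].reset_index(drop=True)


def _traits_by_feature(results: pd.DataFrame) -> dict[str, list[str]]:
    if results is None or results.empty:
        return {}
    sig = results[results["significant"].fillna(False)]
    return {
        fid: sorted(grp["trait"].unique())
        for fid, grp in sig.groupby("feature_id")
    }


def crossref_meqtl(
    snp_results: pd.DataFrame,
    meqtl: pd.DataFrame,
    cpg_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join trait-significant SNPs with the me-QTL reference table.

    One output row per me-QTL pair whose SNP is trait-significant in the
    SNP layer, carrying the SNP's traits and (when EWAS results are given)
    the CpG's traits; rows whose CpG has no trait association are retained
    but flagged ``cpg_has_trait = False``.
    """
    cols = ["mirna_ids", "rsid", "cpg", "cis_trans", "snp_traits",
            "cpg_traits", "cpg_has_trait", "fdr"]
    if meqtl.empty or snp_results.empty:
        return pd.DataFrame(columns=cols)
    snp_traits = _traits_by_feature(snp_results)
    cpg_traits = _traits_by_feature(cpg_results) if cpg_results is not None else {}
    mirna_map = (
        snp_results.drop_duplicates("feature_id")
        .set_index("feature_id")["mirna_ids"]
        .to_dict()
        if "mirna_ids" in snp_results.columns
        else {}
    )
    rows = []
    for r in meqtl.itertuples(index=False):
        if r.rsid not in snp_traits:
            continue
        ctraits = cpg_traits.get(r.cpg, [])
        rows.append(
            {
                "mirna_ids": mirna_map.get(r.rsid, []),
                "rsid": r.rsid,
                "cpg": r.cpg,
                "cis_trans": r.cis_trans,
                "snp_traits": snp_traits[r.rsid],
                "cpg_traits": ctraits,
                "cpg_has_trait": bool(ctraits),
                "fdr": r.fdr,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def crossref_eqtm(
    cpg_results: pd.DataFrame,
    eqtm: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join trait-significant CpGs with the miR-eQTM reference table.

    Emits one row per (CpG, miRNA) pair — a CpG regulating two miRNAs
    yields two rows."""
    cols = ["cpg", "mirna", "direction", "cpg_traits", "fdr"]
    if eqtm.empty or cpg_results.empty:
        return pd.DataFrame(columns=cols)
    cpg_traits = _traits_by_feature(cpg_results)
    rows = [
        {
            "cpg": r.cpg,
            "mirna": r.mirna,
            "direction": r.direction,
            "cpg_traits": cpg_traits[r.cpg],
            "fdr": r.fdr,
        }
        for r in eqtm.itertuples(index=False)
        if r.cpg in cpg_traits
    ]
    return pd.DataFrame(rows, columns=cols)
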