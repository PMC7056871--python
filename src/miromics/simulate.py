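"""Synthetic cohort generator with known planted truth.

Generates internally consistent inputs for every pipeline stage, emulating
the data the analysis was designed for:

* miRNA annotations: precursors with one mature form each, laid out on
  four chromosomes; SNPs and CpG probes placed inside each precursor's
  +/-2 kb window so region annotation is non-trivial.
* genotypes: hard-call dosages {0,1,2} obtained by thresholding latent
  Gaussians with AR(1) correlation within per-miRNA LD blocks at
  Hardy-Weinberg genotype frequencies; blocks are mutually independent.
* GWAS summary statistics: single-variant regressions of each trait on
  each dosage, computed from the simulated genotype/phenotype cohort.
* methylation: beta-values = probe baseline + planted trait effect + batch
  random intercept + noise, clipped to (0, 1).
* miRNA counts: Poisson counts around per-miRNA log2-CPM means, with the
  log-scale SD decreasing in the mean (sd = 2·exp(-mean/3) + 0.2), so the
  LLOQ machinery sees the mean-SD relation it assumes.
* phenotypes: trait values carrying the planted SNP (GWAS cohort),
  CpG (methylation cohort) and expression (expression cohort) effects;
  disease traits via a logistic link at a configurable prevalence.

A *planted* miRNA carries effects for the same trait in all three layers;
every other miRNA is pure noise. The truth tables list every planted
effect. Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomicInterval, MirnaRecord, SiteRecord
from .traits import TRAITS, TRAIT_GROUPS

#: imputation panel assigned to each trait group's GWAS
PANEL_BY_GROUP = {
    "anthropometric": "hapmap",
    "glycemic": "hapmap",
    "lipid": "1000g",
    "cardiovascular": "1000g",
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # cohort sizes (per omics layer, disjoint sample sets as in the study)
    n_samples_gwas: int = 5_000
    n_samples_meth: int = 700
    n_samples_expr: int = 1_000
    # genome layout
    n_mirnas: int = 300
    snps_per_mirna: int = 16
    cpgs_per_mirna: int = 6
    flank_bp: int = 2_000
    # LD and allele frequencies: one latent AR(1) process and one shared
    # minor-allele frequency per block (tight-LD SNPs ride one haplotype,
    # so their allele frequencies track each other)
    ld_rho: float = 0.97
    maf_range: tuple[float, float] = (0.05, 0.5)
    # planted effects
    n_planted_mirnas: int = 10
    snp_beta: float = 0.4
    cpg_effect_sd_multiple: float = 2.0
    expr_effect: float = 0.3
    planted_traits: tuple[str, ...] = ("TC", "LDL", "HDL", "TG", "BMI", "FG")
    # methylation technical structure
    n_batches: int = 10
    batch_sd: float = 0.02
    meth_resid_sd: float = 0.02
    # count model
    n_well_expressed: int = 120
    libsize: int = 5_000_000
    # disease prevalence (logistic link)
    prevalence: dict = field(
        default_factory=lambda: {"T2D": 0.15, "CHD": 0.10}
    )
    # which traits get summary statistics
    traits: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        for name in ("n_samples_gwas", "n_samples_meth", "n_samples_expr",
                     "n_mirnas", "snps_per_mirna", "cpgs_per_mirna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_mirnas > self.n_mirnas:
            raise ValueError(
                "infeasible config: more planted miRNAs than miRNAs"
            )
        if self.n_well_expressed > self.n_mirnas:
            raise ValueError(
                "infeasible config: more well-expressed miRNAs than miRNAs"
            )


@dataclass
class SyntheticCohort:
    """All generated inputs plus the planted-truth tables."""

    config: SimulationConfig
    mirna_records: list[MirnaRecord]
    snp_catalog: list[SiteRecord]
    eqtl_catalog: list[SiteRecord]
    snp_positions: pd.DataFrame  # rsid, chrom, pos, mirna
    genotypes: pd.DataFrame      # samples x rsids
    gwas_phenotypes: pd.DataFrame
    sumstats: pd.DataFrame
    cpg_manifest: list[SiteRecord]
    methylation: pd.DataFrame    # probes x samples
    meth_phenotypes: pd.DataFrame
    counts: pd.DataFrame         # mature miRNAs x samples
    housekeeping: set[str]
    expr_phenotypes: pd.DataFrame
    meqtl: pd.DataFrame
    eqtm: pd.DataFrame
    flags: pd.DataFrame
    truth: dict[str, pd.DataFrame]

    @property
    def mature_to_mirna(self) -> dict[str, str]:
        return {
            mat: rec.mirna_id
            for rec in self.mirna_records
            for mat in rec.mature_ids
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every input in the file format its consuming stage reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        gff = outdir / "mirnas.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, rec in enumerate(self.mirna_records):
                iv = rec.precursor_interval
                s1, e1 = iv.to_1based()
                fh.write(
                    f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{s1}\t{e1}\t.\t"
                    f"{iv.strand}\t.\tID=MI{i:07d};Name={rec.mirna_id}\n"
                )
                for mat_id, mat_iv in zip(rec.mature_ids, rec.mature_intervals):
                    ms1, me1 = mat_iv.to_1based()
                    fh.write(
                        f"{mat_iv.chrom}\t.\tmiRNA\t{ms1}\t{me1}\t.\t"
                        f"{mat_iv.strand}\t.\tID=MIMAT{i:06d};Name={mat_id};"
                        f"Derives_from=MI{i:07d}\n"
                    )
        paths["mirnas.gff3"] = gff

        def catalog_frame(cat: list[SiteRecord]) -> pd.DataFrame:
            return pd.DataFrame(
                [{"rsid": s.site_id, "chrom": s.chrom, "pos": s.pos,
                  "a1": s.alleles[0] if s.alleles else "",
                  "a2": s.alleles[1] if s.alleles else "",
                  "source": sorted(s.sources)[0],
                  "mirna": ";".join(s.mirna_ids)} for s in cat]
            )

        tables = {
            "snp_catalog.tsv": catalog_frame(self.snp_catalog),
            "eqtl_catalog.tsv": catalog_frame(self.eqtl_catalog),
            "sumstats.tsv": self.sumstats,
            "cpg_manifest.tsv": pd.DataFrame(
                [{"probe_id": s.site_id, "chrom": s.chrom, "pos": s.pos}
                 for s in self.cpg_manifest]
            ),
            "meqtl.tsv": self.meqtl,
            "eqtm.tsv": self.eqtm,
            "flags.tsv": self.flags,
        }
        for name, df in tables.items():
            df.to_csv(outdir / name, sep="\t", index=False)
            paths[name] = outdir / name
        self.methylation.to_csv(outdir / "methylation.tsv", sep="\t")
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.meth_phenotypes.to_csv(outdir / "meth_phenotypes.csv")
        self.expr_phenotypes.to_csv(outdir / "expr_phenotypes.csv")
        for layer, df in self.truth.items():
            df.to_csv(outdir / f"truth_{layer}.tsv", sep="\t", index=False)
        for name in ("methylation.tsv", "counts.tsv", "meth_phenotypes.csv",
                     "expr_phenotypes.csv"):
            paths[name] = outdir / name
        return paths


# ---------------------------------------------------------------------------
# building blocks


def _ar1_block(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n x m latent Gaussians with AR(1) column correlation rho."""
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + scale * rng.standard_normal(n)
    return z


def _dosages(z: np.ndarray, mafs: np.ndarray) -> np.ndarray:
    """Threshold latent Gaussians into {0,1,2} at Hardy-Weinberg
    frequencies for the given minor-allele frequencies (per column)."""
    q_hom_ref = stats.norm.ppf((1.0 - mafs) ** 2)  # P(dosage 0)
    q_not_hom_alt = stats.norm.ppf(1.0 - mafs ** 2)  # P(dosage <= 1)
    return ((z > q_hom_ref).astype(np.int8) + (z > q_not_hom_alt)).astype(np.int8)


def single_variant_regression(
    genotypes: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple linear regression of y on dosage (with intercept).

    Vectorized textbook least squares; returns (beta, se, p). Monomorphic
    columns yield NaN."""
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gc.T @ yc / sxx
        sse = (yc * yc).sum() - beta * beta * sxx
        sigma2 = sse / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df=n - 2)
    bad = sxx <= 0
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return beta, se, p


def _base_phenotypes(rng: np.random.Generator, samples: list[str]) -> pd.DataFrame:
    n = len(samples)
    # measured cell proportions: true fractions times assay noise, so the
    # three columns do not sum exactly to one (as in real count data)
    cells = rng.dirichlet([8, 60, 30], size=n)
    cells = np.clip(cells * rng.normal(1.0, 0.05, size=cells.shape), 0.0, None)
    return pd.DataFrame(
        {
            "age": np.round(rng.normal(65, 8, n), 1),
            "sex": rng.integers(0, 2, n),
            "current_smoking": (rng.random(n) < 0.2).astype(int),
            "monocytes": cells[:, 0],
            "granulocytes": cells[:, 1],
            "lymphocytes": cells[:, 2],
            "bmi": np.round(rng.normal(27, 4, n), 2),
            "diabetic_medication": (rng.random(n) < 0.1).astype(int),
            "lipid_medication": (rng.random(n) < 0.25).astype(int),
            "bp_medication": (rng.random(n) < 0.3).astype(int),
        },
        index=pd.Index(samples, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# main generator


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic multi-omics cohort (see module docstring)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # ---- miRNA layout: 4 chromosomes, 50 kb between precursors
    records: list[MirnaRecord] = []
    for i in range(cfg.n_mirnas):
        chrom = str(1 + i % 4)
        start = 100_000 + (i // 4) * 50_000
        end = start + 80
        strand = "+" if i % 2 == 0 else "-"
        precursor = GenomicInterval(chrom, start, end, strand)
        mature = GenomicInterval(chrom, start + 10, start + 32, strand)
        mid = f"mir-s{i:04d}"
        records.append(
            MirnaRecord(
                mirna_id=mid,
                precursor_interval=precursor,
                mature_ids=[f"miR-s{i:04d}-5p"],
                mature_intervals=[mature],
            )
        )

    # ---- SNP catalog: one LD block per miRNA inside its +/-flank window
    n_snps = cfg.n_mirnas * cfg.snps_per_mirna
    block_mafs = rng.uniform(*cfg.maf_range, size=cfg.n_mirnas)
    mafs = np.repeat(block_mafs, cfg.snps_per_mirna)
    snp_rows = []
    k = 0
    for rec in records:
        iv = rec.precursor_interval
        lo, hi = iv.start - cfg.flank_bp, iv.end + cfg.flank_bp
        offsets = np.sort(rng.integers(lo, hi, size=cfg.snps_per_mirna))
        for off in offsets:
            snp_rows.append(
                {"rsid": f"rs{k:07d}", "chrom": iv.chrom, "pos": int(off) + 1,
                 "mirna": rec.mirna_id}
            )
            k += 1
    snp_positions = pd.DataFrame(snp_rows)
    alleles = rng.choice(["A", "C", "G", "T"], size=(n_snps, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    snp_catalog = [
        SiteRecord(site_id=r.rsid, site_kind="snp", chrom=r.chrom, pos=r.pos,
                   alleles=(alleles[i, 0], alleles[i, 1]),
                   sources=frozenset({"region_scan"}))
        for i, r in enumerate(snp_positions.itertuples(index=False))
    ]

    # ---- genotypes: AR(1) within each per-miRNA block
    geno = np.empty((cfg.n_samples_gwas, n_snps), dtype=np.int8)
    for b in range(cfg.n_mirnas):
        sl = slice(b * cfg.snps_per_mirna, (b + 1) * cfg.snps_per_mirna)
        z = _ar1_block(rng, cfg.n_samples_gwas, cfg.snps_per_mirna, cfg.ld_rho)
        geno[:, sl] = _dosages(z, mafs[sl])
    gwas_samples = [f"G{i:05d}" for i in range(cfg.n_samples_gwas)]
    genotypes = pd.DataFrame(geno, index=gwas_samples,
                             columns=snp_positions["rsid"])

    # ---- planted miRNAs and their causal SNPs
    planted_idx = rng.choice(cfg.n_mirnas, size=cfg.n_planted_mirnas,
                             replace=False)
    planted = []
    for j, mi in enumerate(sorted(planted_idx)):
        trait = cfg.planted_traits[j % len(cfg.planted_traits)]
        causal_snp = snp_positions["rsid"].iloc[mi * cfg.snps_per_mirna]
        planted.append(
            {"mirna": records[mi].mirna_id,
             "mature": records[mi].mature_ids[0],
             "trait": trait, "rsid": causal_snp, "mirna_index": mi}
        )
    planted_df = pd.DataFrame(
        planted, columns=["mirna", "mature", "trait", "rsid", "mirna_index"]
    )

    # ---- GWAS phenotypes and summary statistics
    gwas_pheno = _base_phenotypes(rng, gwas_samples)
    snp_truth_rows = []
    trait_values: dict[str, np.ndarray] = {}
    for trait in cfg.traits:
        y = rng.standard_normal(cfg.n_samples_gwas)
        for row in planted:
            if row["trait"] == trait:
                g = genotypes[row["rsid"]].to_numpy(dtype=float)
                y = y + cfg.snp_beta * g
                snp_truth_rows.append(
                    {"rsid": row["rsid"], "trait": trait,
                     "beta": cfg.snp_beta, "mirna": row["mirna"]}
                )
        trait_values[trait] = y
        gwas_pheno[trait] = y

    sum_rows = []
    group_of = {t: g for g, ts in TRAIT_GROUPS.items() for t in ts}
    for trait in cfg.traits:
        beta, se, p = single_variant_regression(geno, trait_values[trait])
        ok = np.isfinite(beta)
        panel = PANEL_BY_GROUP[group_of[trait]]
        sum_rows.append(
            pd.DataFrame(
                {
                    "rsid": snp_positions["rsid"][ok],
                    "trait": trait,
                    "effect_allele": alleles[ok, 0],
                    "other_allele": alleles[ok, 1],
                    "beta": beta[ok],
                    "se": se[ok],
                    "p": np.clip(p[ok], 1e-300, 1.0),
                    "n": cfg.n_samples_gwas,
                    "panel": panel,
                }
            )
        )
    sumstats = pd.concat(sum_rows, ignore_index=True)

    # ---- methylation cohort
    n_cpgs = cfg.n_mirnas * cfg.cpgs_per_mirna
    cpg_rows = []
    k = 0
    for rec in records:
        iv = rec.precursor_interval
        lo, hi = iv.start - cfg.flank_bp, iv.end + cfg.flank_bp
        for off in np.sort(rng.integers(lo, hi, size=cfg.cpgs_per_mirna)):
            cpg_rows.append(
                {"probe_id": f"cg{k:08d}", "chrom": iv.chrom,
                 "pos": int(off) + 1, "mirna": rec.mirna_id}
            )
            k += 1
    cpg_positions = pd.DataFrame(cpg_rows)
    cpg_manifest = [
        SiteRecord(site_id=r.probe_id, site_kind="cpg", chrom=r.chrom,
                   pos=r.pos, sources=frozenset({"manifest"}))
        for r in cpg_positions.itertuples(index=False)
    ]

    meth_samples = [f"M{i:05d}" for i in range(cfg.n_samples_meth)]
    meth_pheno = _base_phenotypes(rng, meth_samples)
    for trait in cfg.traits:
        meth_pheno[trait] = rng.standard_normal(cfg.n_samples_meth)
    batches = rng.integers(0, cfg.n_batches, size=cfg.n_samples_meth)
    meth_pheno["batch"] = [f"plate{b:02d}" for b in batches]
    batch_offsets = rng.normal(0.0, cfg.batch_sd, size=cfg.n_batches)

    base_levels = rng.uniform(0.2, 0.8, size=n_cpgs)
    meth = (
        base_levels[:, None]
        + batch_offsets[batches][None, :]
        + rng.normal(0.0, cfg.meth_resid_sd, size=(n_cpgs, cfg.n_samples_meth))
    )
    cpg_effect = cfg.cpg_effect_sd_multiple * cfg.meth_resid_sd
    cpg_truth_rows = []
    probe_index = {p: i for i, p in enumerate(cpg_positions["probe_id"])}
    for row in planted:
        probe = cpg_positions["probe_id"].iloc[
            row["mirna_index"] * cfg.cpgs_per_mirna
        ]
        t = meth_pheno[row["trait"]].to_numpy()
        meth[probe_index[probe]] += cpg_effect * (t - t.mean()) / t.std()
        cpg_truth_rows.append(
            {"probe_id": probe, "trait": row["trait"], "beta": cpg_effect,
             "mirna": row["mirna"]}
        )
    methylation = pd.DataFrame(
        np.clip(meth, 1e-3, 1 - 1e-3),
        index=cpg_positions["probe_id"], columns=meth_samples,
    )

    # ---- expression cohort: counts with decreasing mean-SD relation
    mature_ids = [rec.mature_ids[0] for rec in records]
    mu = rng.uniform(-2.0, 1.0, size=cfg.n_mirnas)  # low expressers
    well_idx = set(
        rng.choice(cfg.n_mirnas, size=cfg.n_well_expressed, replace=False)
    )
    well_idx |= {row["mirna_index"] for row in planted}  # planted must be testable
    for i in well_idx:
        mu[i] = rng.uniform(4.0, 11.0)
    sd = 2.0 * np.exp(-mu / 3.0) + 0.2

    expr_samples = [f"E{i:05d}" for i in range(cfg.n_samples_expr)]
    x = mu[:, None] + sd[:, None] * rng.standard_normal(
        (cfg.n_mirnas, cfg.n_samples_expr)
    )
    lam = np.maximum(2.0 ** x - 1.0, 0.0) * (cfg.libsize / 1e6)
    counts = pd.DataFrame(
        rng.poisson(lam).astype(np.int64),
        index=mature_ids, columns=expr_samples,
    )
    housekeeping = set()

    expr_pheno = _base_phenotypes(rng, expr_samples)
    expr_truth_rows = []
    zscores = {
        row["mature"]: stats.zscore(x[row["mirna_index"]]) for row in planted
    }
    for trait in cfg.traits:
        y = rng.standard_normal(cfg.n_samples_expr)
        for row in planted:
            if row["trait"] == trait:
                y = y + cfg.expr_effect * zscores[row["mature"]]
                expr_truth_rows.append(
                    {"mature": row["mature"], "trait": trait,
                     "beta": cfg.expr_effect, "mirna": row["mirna"]}
                )
        expr_pheno[trait] = y
    for disease, prev in cfg.prevalence.items():
        lin = np.zeros(cfg.n_samples_expr)
        for row in planted:
            if row["trait"] == disease:
                lin = lin + cfg.expr_effect * zscores[row["mature"]]
        prob = 1.0 / (1.0 + np.exp(-(np.log(prev / (1 - prev)) + lin)))
        expr_pheno[disease] = (rng.random(cfg.n_samples_expr) < prob).astype(int)

    # ---- reference tables: eQTL catalog, me-QTL and eQTM pairs, flags
    eqtl_catalog = []
    meqtl_rows, eqtm_rows = [], []
    for row in planted:
        mi = row["mirna_index"]
        block = snp_positions.iloc[
            mi * cfg.snps_per_mirna: mi * cfg.snps_per_mirna + 2
        ]
        for r in block.itertuples(index=False):
            eqtl_catalog.append(
                SiteRecord(site_id=r.rsid, site_kind="snp", chrom=r.chrom,
                           pos=r.pos, sources=frozenset({"eqtl_catalog"}),
                           mirna_ids=(row["mature"],))
            )
        probe = cpg_positions.iloc[mi * cfg.cpgs_per_mirna]
        snp0 = block.iloc[0]
        meqtl_rows.append(
            {"rsid": snp0.rsid, "snp_chr": snp0.chrom, "snp_pos": snp0.pos,
             "cpg": probe.probe_id, "cpg_chr": probe.chrom,
             "cpg_pos": probe.pos, "fdr": 1e-3}
        )
        eqtm_rows.append(
            {"cpg": probe.probe_id, "mirna": row["mature"],
             "direction": -1, "fdr": 1e-3}
        )
    # distal decoy eQTL SNPs (no overlap with the region scan)
    for j in range(cfg.n_planted_mirnas * 2):
        mat = mature_ids[int(rng.integers(0, cfg.n_mirnas))]
        eqtl_catalog.append(
            SiteRecord(site_id=f"rs9{j:06d}", site_kind="snp", chrom="1",
                       pos=int(5_000_000 + j * 1_000),
                       sources=frozenset({"eqtl_catalog"}), mirna_ids=(mat,))
        )
    meqtl = pd.DataFrame(
        meqtl_rows, columns=["rsid", "snp_chr", "snp_pos", "cpg", "cpg_chr",
                             "cpg_pos", "fdr"]
    )
    if not meqtl.empty:
        from .qtl import classify_cis_trans

        meqtl["cis_trans"] = [
            classify_cis_trans(r.snp_chr, r.snp_pos, r.cpg_chr, r.cpg_pos)
            for r in meqtl.itertuples(index=False)
        ]
    eqtm = pd.DataFrame(eqtm_rows, columns=["cpg", "mirna", "direction", "fdr"])
    flags = pd.DataFrame(
        {
            "mirna": [rec.mirna_id for rec in records],
            "eqtl_evidence": [
                rec.mirna_id in set(planted_df["mirna"]) for rec in records
            ],
            "tissue_expression": [
                rec.mirna_id in set(planted_df["mirna"]) for rec in records
            ],
            "structure_change": False,
        }
    )

    truth = {
        "snp": pd.DataFrame(snp_truth_rows,
                            columns=["rsid", "trait", "beta", "mirna"]),
        "cpg": pd.DataFrame(cpg_truth_rows,
                            columns=["probe_id", "trait", "beta", "mirna"]),
        "expression": pd.DataFrame(expr_truth_rows,
                                   columns=["mature", "trait", "beta", "mirna"]),
        "mirna": planted_df,
    }

    return SyntheticCohort(
        config=cfg,
        mirna_records=records,
        snp_catalog=snp_catalog,
        eqtl_catalog=eqtl_catalog,
        snp_positions=snp_positions,
        genotypes=genotypes,
        gwas_phenotypes=gwas_pheno,
        sumstats=sumstats,
        cpg_manifest=cpg_manifest,
        methylation=methylation,
        meth_phenotypes=meth_pheno,
        counts=counts,
        housekeeping=housekeeping,
        expr_phenotypes=expr_pheno,
        meqtl=meqtl,
        eqtm=eqtm,
        flags=flags,
        truth=truth,
    )
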