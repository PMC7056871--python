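"""Plasma miRNA expression: normalization, LLOQ filtering, association.

Counts are normalized to counts-per-million (CPM) and log2-transformed with
a pseudocount of 1, so zero counts map to 0 on the log2 scale. The lower
limit of quantification (LLOQ) is derived from the mean–SD relation across
miRNAs: on the log2-CPM scale the per-miRNA standard deviation decreases
with the mean, and an antitonic (monotone non-increasing) regression of SD
on mean, lightly smoothed, is inverted at a configurable SD cut (default:
midpoint of the fitted SD range). A miRNA is well-expressed when strictly
more than ``min_frac`` (default 50%) of its samples exceed the LLOQ; an
independent hard floor (default log2 CPM < 1 means "not expressed") is
applied first.

Associations put the *trait* on the left-hand side: continuous traits use
ordinary linear models, disease-prevalence traits (T2D, CHD) binomial
(logistic) models, both with the trait group's covariates (age, sex,
current smoking as the base set).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.isotonic import IsotonicRegression
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .gwas import bonferroni_threshold, test_gwas_associations
from .annotation import GenomicInterval, map_sites_to_regions
from .methylation import covariates_for_trait

log = logging.getLogger(__name__)

NOMINAL_ALPHA = 0.05

#: disease-prevalence outcomes modelled with a binomial link in this layer
DISEASE_TRAITS = frozenset({"T2D", "CHD"})
DEFAULT_EXPRESSED_FLOOR = 1.0  # log2 CPM below this means "not expressed"


def cpm_log2(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) matrix (miRNAs x samples).

    Per-sample CPM columns sum to 1e6 before the pseudocount. All-zero
    samples are rejected by name.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    totals = mat.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise ValueError(
            f"all-zero sample(s): {list(counts.columns[zero])}"
        )
    cpm = mat / totals * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index,
                        columns=counts.columns)


@dataclass
class NormalizationInfo:
    """Normalization products: log2-CPM, per-miRNA moments, LLOQ, filters."""

    log2cpm: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    lloq: float
    well_expressed: set[str]
    expressed_floor: float = DEFAULT_EXPRESSED_FLOOR
    housekeeping: set[str] = field(default_factory=set)


def antitonic_fit(means: np.ndarray, sds: np.ndarray,
                  smooth_window: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Monotone non-increasing fit of SD on mean.

    Means are sorted ascending; an antitonic (decreasing isotonic)
    regression is applied, then a centered moving average (which preserves
    monotonicity) lightly smooths step artifacts. Returns (sorted means,
    fitted SDs).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    order = np.argsort(means, kind="mergesort")
    x, y = means[order], sds[order]
    fit = IsotonicRegression(increasing=False).fit_transform(x, y)
    n = len(fit)
    if smooth_window is None:
        smooth_window = max(3, n // 50) | 1  # odd
    if smooth_window > 1 and n >= smooth_window:
        pad = smooth_window // 2
        padded = np.concatenate([np.full(pad, fit[0]), fit, np.full(pad, fit[-1])])
        kernel = np.ones(smooth_window) / smooth_window
        fit = np.convolve(padded, kernel, mode="valid")
    return x, fit


def fit_lloq(
    means: pd.Series | np.ndarray,
    sds: pd.Series | np.ndarray,
    sd_cut: float | None = None,
) -> float:
    """LLOQ on the log2-CPM scale from the mean–SD profile.

    Fits the non-increasing mean->SD curve and returns the smallest mean at
    which the fitted SD drops to ``sd_cut`` or below. By default the cut is
    the midpoint of the fitted curve's range (scale-free). A flat SD
    profile is degenerate: the minimum observed mean is returned with a
    warning.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ok = np.isfinite(means) & np.isfinite(sds)
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 finite mean/SD pairs, got {int(ok.sum())}")
    x, fit = antitonic_fit(means[ok], sds[ok])
    lo, hi = float(fit.min()), float(fit.max())
    if hi - lo < 1e-12:
        log.warning("LLOQ degenerate: flat SD profile; returning min mean")
        return float(x.min())
    c = (lo + hi) / 2 if sd_cut is None else sd_cut
    below = fit <= c
    if not below.any():
        log.warning("no fitted SD at or below the cut; returning max mean")
        return float(x.max())
    return float(x[below].min())


def well_expressed(
    log2cpm: pd.DataFrame, lloq: float, min_frac: float = 0.5
) -> set[str]:
    """miRNAs with strictly more than ``min_frac`` of samples above LLOQ
    (strict inequalities on both comparisons)."""
    if not np.isfinite(lloq):
        raise ValueError("lloq must be finite")
    frac_above = (log2cpm > lloq).mean(axis=1)
    return set(log2cpm.index[frac_above > min_frac])


def normalize_counts(
    counts: pd.DataFrame,
    housekeeping: set[str] | None = None,
    expressed_floor: float = DEFAULT_EXPRESSED_FLOOR,
    min_frac: float = 0.5,
    sd_cut: float | None = None,
) -> NormalizationInfo:
    """Full normalization: CPM/log2, floor filter, LLOQ fit, expression filter.

    Housekeeping probes are normalized alongside the rest but excluded from
    the LLOQ fit and from the well-expressed set. The hard expression floor
    (mean log2 CPM >= ``expressed_floor``) and the LLOQ filter are applied
    sequentially as two independent criteria.
    """
    housekeeping = housekeeping or set()
    log2cpm = cpm_log2(counts)
    means = log2cpm.mean(axis=1)
    sds = log2cpm.std(axis=1, ddof=1)
    biological = [m for m in log2cpm.index if m not in housekeeping]
    lloq = fit_lloq(means[biological], sds[biological], sd_cut=sd_cut)
    floored = {m for m in biological if means[m] >= expressed_floor}
    above = well_expressed(log2cpm.loc[biological], lloq, min_frac=min_frac)
    return NormalizationInfo(
        log2cpm=log2cpm,
        means=means,
        sds=sds,
        lloq=lloq,
        well_expressed=floored & above,
        expressed_floor=expressed_floor,
        housekeeping=set(housekeeping),
    )


def test_expression_association(
    mirna_values: pd.Series,
    trait: str,
    phenotypes: pd.DataFrame,
) -> dict:
    """Associate one miRNA's log2-CPM values with a trait.

    The trait is the dependent variable and the miRNA level the explanatory
    one; continuous traits use OLS, T2D/CHD logistic regression (the
    coefficient is then on the log-odds scale). Returns an
    AssociationResult-style dict (layer ``expression``); complete
    separation in the logistic fit yields p = NaN with a flag.
    """
    spec = covariates_for_trait(trait, cell_counts=False)
    covars = [c for c in spec.fixed if c in phenotypes.columns]
    df = pd.DataFrame({"x": mirna_values, "y": phenotypes[trait]})
    df = pd.concat([df, phenotypes[covars]], axis=1).dropna()
    if df["x"].nunique() <= 1 or df["y"].nunique() <= 1:
        raise ValueError("degenerate input: constant miRNA or trait")
    X = sm.add_constant(df[["x"] + [c for c in covars if df[c].nunique() > 1]])

    result = {
        "feature_id": str(mirna_values.name), "trait": trait,
        "layer": "expression", "n": len(df),
        "threshold": NOMINAL_ALPHA, "separation": False,
    }
    if trait in DISEASE_TRAITS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation handled below
                fit = sm.Logit(df["y"], X).fit(disp=0)
            if not np.isfinite(fit.bse["x"]) or fit.bse["x"] > 1e3:
                raise PerfectSeparationError
        except (PerfectSeparationError, np.linalg.LinAlgError):
            log.warning("separation in logistic fit for %s/%s",
                        mirna_values.name, trait)
            result.update(beta=np.nan, se=np.nan, p=np.nan,
                          separation=True, significant=False)
            return result
    else:
        fit = sm.OLS(df["y"], X).fit()
    p = float(fit.pvalues["x"])
    result.update(
        beta=float(fit.params["x"]), se=float(fit.bse["x"]), p=p,
        significant=p < NOMINAL_ALPHA,
    )
    return result


def run_expression_associations(
    log2cpm: pd.DataFrame,
    phenotypes: pd.DataFrame,
    candidate_mirnas: list[str],
    traits: list[str],
) -> pd.DataFrame:
    """Candidate-based expression testing: candidate miRNAs x traits.

    Only miRNAs present in the matrix and traits present in the phenotype
    table are tested (others are untested, not failed)."""
    shared = log2cpm.columns.intersection(phenotypes.index)
    if len(shared) == 0:
        raise ValueError("no overlapping samples between expression and phenotypes")
    expr = log2cpm[shared]
    pheno = phenotypes.loc[shared]
    rows = []
    for mirna in candidate_mirnas:
        if mirna not in expr.index:
            continue
        for trait in traits:
            if trait not in pheno.columns:
                continue
            try:
                rows.append(
                    test_expression_association(expr.loc[mirna], trait, pheno)
                )
            except ValueError as exc:
                log.warning("skipping %s/%s: %s", mirna, trait, exc)
    cols = ["feature_id", "trait", "layer", "beta", "se", "p", "n",
            "threshold", "significant", "separation"]
    return pd.DataFrame(rows, columns=cols)


def target_gene_lookup(
    gene_intervals: list[tuple[str, GenomicInterval]],
    gene_to_mirna: dict[str, list[str]],
    snp_sites: list,
    sumstats: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test SNPs inside validated target genes of a miRNA against GWAS stats.

    Reuses the region-mapping and GWAS lookup machinery on gene intervals;
    the Bonferroni denominator is per miRNA — the number of SNPs tested
    within that miRNA's target genes.
    """
    regions = [(gene, "flank", iv) for gene, iv in gene_intervals]
    hits = map_sites_to_regions(snp_sites, regions)
    if not hits:
        return pd.DataFrame(
            columns=["feature_id", "mirna_ids", "trait", "layer", "beta",
                     "se", "p", "n", "threshold", "significant", "gene"]
        )
    rows = []
    for ann in hits:
        for gene in ann.mirna_ids:  # gene names occupy the miRNA slot here
            for mirna in gene_to_mirna.get(gene, []):
                rows.append({"site_id": ann.site_id, "gene": gene,
                             "mirna_id": mirna})
    ann_df = pd.DataFrame(rows)
    out = []
    for mirna, grp in ann_df.groupby("mirna_id"):
        snps = grp["site_id"].unique()
        sub = sumstats[sumstats["rsid"].isin(snps)].copy()
        if sub.empty:
            continue
        m = sub["rsid"].nunique()
        thr = bonferroni_threshold(alpha, m)
        sub["panel"] = sub["panel"].fillna("unknown")
        panel_thresholds = {p: thr for p in sub["panel"].unique()}
        res = test_gwas_associations(
            grp.rename(columns={"mirna_id": "mirna_id"})[["site_id", "mirna_id"]],
            sub, panel_thresholds,
        )
        res["gene"] = res["feature_id"].map(
            grp.drop_duplicates("site_id").set_index("site_id")["gene"]
        )
        out.append(res)
    if not out:
        return pd.DataFrame(
            columns=["feature_id", "mirna_ids", "trait", "layer", "beta",
                     "se", "p", "n", "threshold", "significant", "gene"]
        )
    return pd.concat(out, ignore_index=True)


def expression_qc_table(info: NormalizationInfo) -> pd.DataFrame:
    """Per-miRNA QC: mean, SD, housekeeping flag, well-expressed flag."""
    return pd.DataFrame(
        {
            "mirna": info.log2cpm.index,
            "mean_log2cpm": info.means.to_numpy(),
            "sd_log2cpm": info.sds.to_numpy(),
            "housekeeping": [m in info.housekeeping for m in info.log2cpm.index],
            "well_expressed": [m in info.well_expressed for m in info.log2cpm.index],
        }
    )
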