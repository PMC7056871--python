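"""Candidate SNP testing against GWAS summary statistics.

The candidate SNPs (annotated to miRNA regions or miR-eQTL catalogs) are
looked up in per-trait summary-statistic tables. Multiple testing is
controlled family-wise with a Bonferroni threshold whose denominator is the
number of *independent* SNPs, obtained by greedy windowed LD pruning at
r² > r2_max (default 0.7). Thresholds are computed per imputation panel
(HapMap vs 1000G), on the SNPs actually present in that panel's GWAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PANELS = ("hapmap", "1000g")

#: canonical summary-stat columns
SUMSTAT_COLUMNS = [
    "rsid", "trait", "effect_allele", "other_allele",
    "beta", "se", "p", "n", "panel",
]

_HEADER_ALIASES = {
    "rsid": {"rsid", "snp", "snpid", "markername", "variant_id", "id"},
    "trait": {"trait", "phenotype"},
    "effect_allele": {"effect_allele", "a1", "allele1", "ea"},
    "other_allele": {"other_allele", "a2", "allele2", "oa", "nea"},
    "beta": {"beta", "effect", "b"},
    "se": {"se", "stderr", "standard_error"},
    "p": {"p", "pval", "pvalue", "p_value", "p-value"},
    "n": {"n", "samplesize", "n_samples"},
    "panel": {"panel"},
}

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

#: floor applied to p = 0 for -log10 plotting only; significance calls use
#: the raw value.
P_PLOT_FLOOR = 1e-300


@dataclass
class LdMatrix:
    """Pairwise squared-correlation matrix over an ordered rsID list."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        if r2.shape != (len(self.rsids), len(self.rsids)):
            raise ValueError("r2 shape does not match rsid count")
        if not np.allclose(r2, r2.T, equal_nan=True):
            raise ValueError("r2 matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmax(r2) > 1 + 1e-9 or np.nanmin(r2) < -1e-9:
                raise ValueError("r2 values must lie in [0, 1]")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        self.r2 = r2
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def value(self, a: str, b: str) -> float:
        """r² for a pair; missing entries count as independent (0)."""
        try:
            v = self.r2[self._index[a], self._index[b]]
        except KeyError:
            log.warning("missing LD entry for (%s, %s); treating as 0", a, b)
            return 0.0
        if np.isnan(v):
            log.warning("missing LD value for (%s, %s); treating as 0", a, b)
            return 0.0
        return float(v)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m for m independent tests."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1]: {alpha}")
    if m < 1 or int(m) != m:
        raise ValueError(f"m must be a positive integer: {m}")
    return alpha / m


def ld_prune(
    rsids: list[str],
    ld: LdMatrix,
    r2_max: float = 0.7,
    window_bp: int = 250_000,
    positions: dict[str, int] | None = None,
) -> list[str]:
    """Greedy position-ordered sliding-window LD pruning.

    Within each window (length ``window_bp``, step half a window), while any
    surviving pair has r² > ``r2_max``, the worst pair's member with the
    larger position-order index is dropped (ties on r² broken by the smaller
    first index, then smaller second index — fully deterministic). The
    returned list preserves the input order of the survivors.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    if not rsids:
        return []
    if positions is None:
        positions = {r: i for i, r in enumerate(rsids)}
    # position-order index: ties on position broken by input order
    order = sorted(range(len(rsids)), key=lambda i: (positions[rsids[i]], i))
    rank = {i: k for k, i in enumerate(order)}
    pos_sorted = np.array([positions[rsids[i]] for i in order], dtype=float)
    kept = set(range(len(rsids)))

    # r2 lookup in position order, missing entries -> 0 (independent)
    n = len(rsids)
    sub = np.zeros((n, n))
    have = [k for k, i in enumerate(order) if rsids[i] in ld._index]
    if len(have) < n:
        log.warning("LD matrix missing %d of %d rsids; treating as independent",
                    n - len(have), n)
    ld_idx = [ld._index[rsids[order[k]]] for k in have]
    block = ld.r2[np.ix_(ld_idx, ld_idx)]
    sub[np.ix_(have, have)] = np.nan_to_num(block, nan=0.0)
    np.fill_diagonal(sub, 0.0)

    lo, hi = pos_sorted[0], pos_sorted[-1]
    step = max(window_bp // 2, 1)
    wstart = lo
    while True:
        a = int(np.searchsorted(pos_sorted, wstart, side="left"))
        b = int(np.searchsorted(pos_sorted, wstart + window_bp, side="right"))
        ranks = [k for k in range(a, b) if order[k] in kept]
        if len(ranks) >= 2:
            w = sub[np.ix_(ranks, ranks)].copy()
            while True:
                flat = int(np.argmax(w))
                i, j = divmod(flat, len(ranks))
                if w[i, j] <= r2_max:
                    break
                drop = max(i, j)  # larger position-order index
                w[drop, :] = 0.0
                w[:, drop] = 0.0
                kept.discard(order[ranks[drop]])
        if wstart + window_bp >= hi:
            break
        wstart += step
    return [r for i, r in enumerate(rsids) if i in kept]


def empirical_r2(genotypes: np.ndarray, rsids: list[str]) -> LdMatrix:
    """LD matrix of squared Pearson correlations from a dosage matrix
    (samples x SNPs). Monomorphic SNPs get r² = 0 off-diagonal."""
    g = np.asarray(genotypes, dtype=float)
    sd = g.std(axis=0)
    ok = sd > 0
    r2 = np.zeros((g.shape[1], g.shape[1]))
    if ok.any():
        c = np.corrcoef(g[:, ok], rowvar=False)
        r2[np.ix_(ok, ok)] = np.square(c)
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(rsids=list(rsids), r2=np.clip(r2, 0.0, 1.0))


def read_sumstats(
    path, trait: str | None = None, panel: str | None = None,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a summary-statistic TSV, tolerant of common header dialects.

    An explicit ``column_map`` (canonical name -> file column) overrides
    sniffing. ``trait``/``panel`` fill in columns absent from the file.
    """
    df = pd.read_csv(path, sep="\t")
    rename: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for canon, aliases in _HEADER_ALIASES.items():
        if column_map and canon in column_map:
            rename[column_map[canon]] = canon
            continue
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canon
                break
    df = df.rename(columns=rename)
    if trait is not None:
        df["trait"] = trait
    if panel is not None:
        df["panel"] = panel
    missing = {"rsid", "trait", "beta", "p"} - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
    for col in SUMSTAT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[SUMSTAT_COLUMNS]


def validate_sumstats(sumstats: pd.DataFrame) -> None:
    dup = sumstats.duplicated(subset=["rsid", "trait"], keep=False)
    if dup.any():
        pairs = sumstats.loc[dup, ["rsid", "trait"]].drop_duplicates()
        raise ValueError(
            "duplicate (rsid, trait) rows in summary statistics: "
            + ", ".join(f"{r.rsid}/{r.trait}" for r in pairs.itertuples())
        )
    bad_p = ~((sumstats["p"] > 0) & (sumstats["p"] <= 1))
    if bad_p.any():
        raise ValueError(
            f"p-values outside (0, 1] for rsids: "
            f"{sorted(sumstats.loc[bad_p, 'rsid'].unique()[:10])}"
        )


def _harmonize(annot: pd.DataFrame, merged: pd.DataFrame) -> pd.DataFrame:
    """Flip beta when effect/other alleles are swapped relative to the
    catalog; drop strand-ambiguous mismatches."""
    if "a1" not in annot.columns or merged["effect_allele"].isna().all():
        return merged
    keep = np.ones(len(merged), dtype=bool)
    beta = merged["beta"].to_numpy(copy=True)
    for i, row in enumerate(merged.itertuples(index=False)):
        a1, a2 = getattr(row, "a1", None), getattr(row, "a2", None)
        ea, oa = row.effect_allele, row.other_allele
        if not (isinstance(a1, str) and isinstance(ea, str) and isinstance(oa, str)):
            continue
        if (ea, oa) == (a1, a2):
            continue
        if frozenset({a1, a2}) in _AMBIGUOUS or frozenset({ea, oa}) in _AMBIGUOUS:
            # an A/T or C/G swap is indistinguishable from a strand flip
            log.warning("dropping strand-ambiguous allele mismatch for %s", row.rsid)
            keep[i] = False
        elif (ea, oa) == (a2, a1):
            beta[i] = -beta[i]
        else:
            log.warning("allele mismatch for %s (%s/%s vs %s/%s); dropped",
                        row.rsid, a1, a2, ea, oa)
            keep[i] = False
    merged = merged.loc[keep].copy()
    merged["beta"] = beta[keep]
    return merged


def test_gwas_associations(
    annotations: pd.DataFrame,
    sumstats: pd.DataFrame,
    panel_thresholds: dict[str, float],
) -> pd.DataFrame:
    """Join annotated SNPs with summary statistics and flag significance.

    ``annotations`` is the long-format annotation table (``site_id``,
    ``mirna_id``, optionally ``a1``/``a2``/``pos``). Each (SNP, trait) pair
    present in the summary statistics is tested against the Bonferroni
    threshold of that GWAS's imputation panel; SNPs absent from a GWAS are
    simply untested for that trait. Returns AssociationResult rows
    (layer ``snp``).
    """
    validate_sumstats(sumstats)
    if annotations.empty or sumstats.empty:
        return _empty_results()
    ann = annotations.rename(columns={"site_id": "rsid"})
    agg = {"mirna_id": lambda s: sorted(set(s))}
    for extra in ("pos", "chrom", "a1", "a2"):
        if extra in ann.columns:
            agg[extra] = "first"
    ann = ann.groupby("rsid", as_index=False).agg(agg)
    ann = ann.rename(columns={"mirna_id": "mirna_ids"})
    merged = ann.merge(sumstats, on="rsid", how="inner")
    merged = _harmonize(ann, merged)
    if merged.empty:
        return _empty_results()
    thr = merged["panel"].map(panel_thresholds)
    if thr.isna().any():
        missing = sorted(merged.loc[thr.isna(), "panel"].astype(str).unique())
        raise ValueError(f"no threshold supplied for panel(s): {missing}")
    out = pd.DataFrame(
        {
            "feature_id": merged["rsid"],
            "mirna_ids": merged["mirna_ids"],
            "trait": merged["trait"],
            "layer": "snp",
            "beta": merged["beta"],
            "se": merged["se"],
            "p": merged["p"],
            "n": merged["n"],
            "threshold": thr.to_numpy(),
            "significant": (merged["p"] < thr).to_numpy(),
        }
    )
    if "pos" in merged.columns:
        out["pos"] = merged["pos"]
    if "chrom" in merged.columns:
        out["chrom"] = merged["chrom"]
    return out


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["feature_id", "mirna_ids", "trait", "layer", "beta", "se",
                 "p", "n", "threshold", "significant"]
    )


def summarize_by_mirna(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(miRNA, trait) locus summary: the most significant SNP represents
    the locus; ties on p broken by smaller position, then rsid."""
    if results.empty:
        return pd.DataFrame(
            columns=["mirna_id", "trait", "feature_id", "beta", "se", "p", "pos"]
        )
    sig = results[results["significant"]].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=["mirna_id", "trait", "feature_id", "beta", "se", "p", "pos"]
        )
    sig = sig.explode("mirna_ids").rename(columns={"mirna_ids": "mirna_id"})
    for optional in ("beta", "se"):
        if optional not in sig.columns:
            sig[optional] = np.nan
    if "pos" not in sig.columns:
        sig["pos"] = np.inf
    sig = sig.sort_values(["p", "pos", "feature_id"], kind="mergesort")
    top = sig.groupby(["mirna_id", "trait"], as_index=False).first()
    return top[["mirna_id", "trait", "feature_id", "beta", "se", "p", "pos"]]


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: chrom, pos, -log10 p (p=0 floored), miRNA id."""
    res = results.explode("mirna_ids").rename(columns={"mirna_ids": "mirna_id"})
    p = res["p"].clip(lower=P_PLOT_FLOOR)
    out = pd.DataFrame(
        {
            "chrom": res.get("chrom", pd.Series("NA", index=res.index)),
            "pos": res.get("pos", pd.Series(np.nan, index=res.index)),
            "neglog10_p": -np.log10(p),
            "mirna_id": res["mirna_id"],
        }
    )
    return out.reset_index(drop=True)
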