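"""EWAS stage: CpG methylation vs cardiometabolic traits.

Methylation beta-values of candidate CpGs (those annotated to miRNA regions)
are regressed on each trait with linear mixed models: the trait and the
trait-group-specific fixed covariates enter as fixed effects, and the
technical batch enters as a random intercept (REML). When the estimated
batch variance is degenerate the fit falls back to ordinary least squares
with batch as a fixed factor, and the fallback is recorded.

Methylation is the dependent variable throughout this stage — the technical
random effects act on the measurement — while the expression stage uses the
opposite orientation (trait as outcome).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .traits import trait_group

log = logging.getLogger(__name__)

#: covariates present in every model (cell counts measured in whole blood)
BASE_COVARIATES = (
    "age", "sex", "current_smoking", "monocytes", "granulocytes", "lymphocytes",
)

NOMINAL_ALPHA = 0.05

#: below this batch-variance estimate the random intercept is considered
#: degenerate and the model falls back to fixed-effect OLS
_VAR_DEGENERATE = 1e-8


@dataclass(frozen=True)
class CovariateSpec:
    """Fixed and random covariates for one trait's association models."""

    trait: str
    fixed: tuple[str, ...]
    random: tuple[str, ...] = ("batch",)


def covariates_for_trait(trait: str, cell_counts: bool = True) -> CovariateSpec:
    """Covariate set for a trait, following the trait-group ledger.

    Base: age, sex, current smoking (plus blood cell counts in the
    methylation stage). Group additions: anthropometric — BMI for WC/WHR
    only (BMI never adjusts for itself); glycemic — BMI + diabetic
    medication; lipid — BMI + lipid medication; cardiovascular — BMI +
    blood-pressure-lowering + lipid medication.
    """
    group = trait_group(trait)  # raises KeyError on unknown trait
    fixed = list(BASE_COVARIATES if cell_counts else BASE_COVARIATES[:3])
    if group == "anthropometric":
        if trait in ("WC", "WHR"):
            fixed.append("bmi")
    elif group == "glycemic":
        fixed += ["bmi", "diabetic_medication"]
    elif group == "lipid":
        fixed += ["bmi", "lipid_medication"]
    elif group == "cardiovascular":
        fixed += ["bmi", "bp_medication", "lipid_medication"]
    return CovariateSpec(trait=trait, fixed=tuple(fixed))


@dataclass
class CpgFit:
    """Result of one (probe, trait) mixed-model fit."""

    beta: float
    se: float
    p: float
    n: int
    used_fallback: bool = False


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        cols: list[str] = []
        for c in X.columns:
            cols.append(c)
            if np.linalg.matrix_rank(X[cols].to_numpy()) < len(cols):
                collinear.append(c)
                cols.pop()
        raise ValueError(f"singular design; collinear columns: {collinear}")


def fit_cpg_trait_model(
    probe_values: pd.Series,
    trait_values: pd.Series,
    covariates: pd.DataFrame,
    batch: pd.Series,
    min_samples: int = 30,
) -> CpgFit:
    """Fit methylation ~ trait + covariates with a per-batch random intercept.

    Complete-case analysis; returns the trait coefficient, its standard
    error and a two-sided Wald p-value. REML fitting; a degenerate batch
    variance (or failed convergence) triggers an OLS fallback with batch as
    a fixed factor.
    """
    df = pd.DataFrame({"y": probe_values, "x": trait_values, "batch": batch})
    df = pd.concat([df, covariates], axis=1).dropna()
    if len(df) < min_samples:
        raise ValueError(
            f"only {len(df)} complete cases (< {min_samples} required)"
        )
    if df["y"].nunique() <= 1 or df["x"].nunique() <= 1:
        raise ValueError("degenerate input: constant probe or trait")

    covar_cols = [c for c in covariates.columns if df[c].nunique() > 1]
    X = sm.add_constant(df[["x"] + covar_cols])
    _check_design(X)

    single_batch = df["batch"].nunique() <= 1
    if not single_batch:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df["y"], X, groups=df["batch"])
            try:
                res = model.fit(reml=True, method="lbfgs")
                var_re = float(np.squeeze(res.cov_re))
                converged = bool(res.converged)
            except (np.linalg.LinAlgError, ValueError):
                var_re, converged = 0.0, False
        if converged and var_re > _VAR_DEGENERATE:
            return CpgFit(
                beta=float(res.params["x"]),
                se=float(res.bse["x"]),
                p=float(res.pvalues["x"]),
                n=len(df),
            )
        log.debug("batch variance degenerate; falling back to fixed-effect OLS")

    if not single_batch:
        dummies = pd.get_dummies(df["batch"], prefix="batch", drop_first=True,
                                 dtype=float)
        X = pd.concat([X, dummies], axis=1)
    ols = sm.OLS(df["y"], X).fit()
    return CpgFit(
        beta=float(ols.params["x"]),
        se=float(ols.bse["x"]),
        p=float(ols.pvalues["x"]),
        n=len(df),
        used_fallback=True,
    )


@dataclass
class EwasLog:
    """Per-run bookkeeping: sample sizes, fallbacks, skipped fits."""

    n_fits: int = 0
    n_fallbacks: int = 0
    skipped: list[tuple[str, str, str]] = field(default_factory=list)


def run_ewas(
    methylation: pd.DataFrame,
    phenotypes: pd.DataFrame,
    candidate_probes: list[str],
    traits: list[str],
    batch_col: str = "batch",
    nominal_alpha: float = NOMINAL_ALPHA,
) -> tuple[pd.DataFrame, EwasLog]:
    """EWAS over candidate probes x traits (candidate-based, nominal 0.05).

    ``methylation`` is probes x samples (beta-values in [0, 1]);
    ``phenotypes`` is indexed by sample id and carries traits, covariates
    and the technical batch label. Returns AssociationResult rows (layer
    ``cpg``) and a run log.
    """
    if ((methylation < 0) | (methylation > 1)).any().any():
        raise ValueError("methylation beta-values must lie in [0, 1]")
    shared = methylation.columns.intersection(phenotypes.index)
    if len(shared) == 0:
        raise ValueError("no overlapping samples between methylation and phenotypes")
    meth = methylation[shared]
    pheno = phenotypes.loc[shared]
    if pheno[batch_col].isna().any():
        raise ValueError("batch label missing for some samples")

    runlog = EwasLog()
    rows = []
    probes = [p for p in candidate_probes if p in meth.index]
    for trait in traits:
        spec = covariates_for_trait(trait)
        covars = [c for c in spec.fixed if c in pheno.columns]
        for probe in probes:
            try:
                fit = fit_cpg_trait_model(
                    meth.loc[probe], pheno[trait], pheno[covars],
                    pheno[batch_col],
                )
            except ValueError as exc:
                runlog.skipped.append((probe, trait, str(exc)))
                continue
            runlog.n_fits += 1
            runlog.n_fallbacks += int(fit.used_fallback)
            rows.append(
                {
                    "feature_id": probe,
                    "trait": trait,
                    "layer": "cpg",
                    "beta": fit.beta,
                    "se": fit.se,
                    "p": fit.p,
                    "n": fit.n,
                    "threshold": nominal_alpha,
                    "significant": fit.p < nominal_alpha,
                    "used_fallback": fit.used_fallback,
                }
            )
    cols = ["feature_id", "trait", "layer", "beta", "se", "p", "n",
            "threshold", "significant", "used_fallback"]
    return pd.DataFrame(rows, columns=cols), runlog
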