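"""Shared fixtures: a small synthetic cohort and large null-model p-value
batches (computed once per session, consumed by both the module property
tests and the acceptance suite)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from miromics import SimulationConfig, simulate_cohort
from miromics.expression import test_expression_association
from miromics.methylation import fit_cpg_trait_model

SMALL_CONFIG = dict(
    n_mirnas=60,
    snps_per_mirna=10,
    cpgs_per_mirna=4,
    n_samples_gwas=2_000,
    n_samples_meth=300,
    n_samples_expr=500,
    n_planted_mirnas=6,
    n_well_expressed=30,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-truth cohort small enough for end-to-end runs in tests."""
    return simulate_cohort(SimulationConfig(seed=7, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects anywhere (pure noise)."""
    cfg = dict(SMALL_CONFIG, n_planted_mirnas=0)
    return simulate_cohort(SimulationConfig(seed=11, **cfg))


@pytest.fixture(scope="session")
def ewas_null_pvalues():
    """2,000 mixed-model p-values for (probe, trait) pairs generated under
    the null: methylation = baseline + batch intercept + noise, trait
    independent of methylation."""
    rng = np.random.default_rng(2024)
    n, n_batches = 700, 10  # the methylation sub-cohort scale the generator emulates
    pvals = []
    for _ in range(2_000):
        batch = rng.integers(0, n_batches, n)
        offsets = rng.normal(0.0, 0.02, n_batches)
        y = pd.Series(0.5 + offsets[batch] + rng.normal(0.0, 0.02, n))
        x = pd.Series(rng.standard_normal(n))
        fit = fit_cpg_trait_model(
            y, x, pd.DataFrame(index=y.index), pd.Series(batch)
        )
        pvals.append(fit.p)
    return np.array(pvals)


@pytest.fixture(scope="session")
def expression_null_pvalues():
    """2,000 expression-model p-values under the null: trait independent of
    the miRNA level (age/sex/smoking covariates present)."""
    rng = np.random.default_rng(2025)
    n = 200
    pvals = []
    for _ in range(2_000):
        pheno = pd.DataFrame(
            {
                "TC": rng.standard_normal(n),
                "age": rng.normal(65, 8, n),
                "sex": rng.integers(0, 2, n),
                "current_smoking": (rng.random(n) < 0.2).astype(int),
                "bmi": rng.normal(27, 4, n),
                "lipid_medication": (rng.random(n) < 0.25).astype(int),
            }
        )
        x = pd.Series(rng.standard_normal(n), name="miR-null")
        pvals.append(test_expression_association(x, "TC", pheno)["p"])
    return np.array(pvals)


def binomial_99ci(p: float, n: int) -> tuple[float, float]:
    half = 2.5758 * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
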