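"""Shared fixtures: small seeded synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aim_mr.datatypes import GenotypeMatrix
from aim_mr.synthetic import (
    SimulationConfig,
    simulate_admixed_cohort,
    simulate_reference_panel,
)


def make_summary_stats(
    variants,
    beta,
    se,
    eaf=None,
    effect_allele="A",
    other_allele="G",
    n=1000,
) -> pd.DataFrame:
    """Build a summary-statistics frame with valid schema from vectors."""
    from scipy import stats as sps

    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    m = len(beta)
    if eaf is None:
        eaf = np.full(m, 0.3)
    if isinstance(effect_allele, str):
        effect_allele = [effect_allele] * m
    if isinstance(other_allele, str):
        other_allele = [other_allele] * m
    return pd.DataFrame(
        {
            "variant": list(variants),
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": 2 * sps.norm.sf(np.abs(beta / se)),
            "n": n,
        }
    )


def make_two_sample_stats(
    rng: np.random.Generator,
    n_instruments: int = 50,
    theta: float = 0.5,
    pleiotropy_sd: float = 0.0,
    se_outcome: float = 0.05,
):
    """Seeded exposure/outcome summary stats with a known causal slope."""
    bx = rng.uniform(0.5, 2.0, n_instruments) * rng.choice([-1, 1], n_instruments)
    sx = rng.uniform(0.02, 0.05, n_instruments)
    alpha = rng.normal(0, pleiotropy_sd, n_instruments)
    by = theta * bx + alpha + rng.normal(0, se_outcome, n_instruments)
    sy = np.full(n_instruments, se_outcome)
    variants = [f"rs{i:04d}" for i in range(n_instruments)]
    exp = make_summary_stats(variants, bx, sx)
    out = make_summary_stats(variants, by, sy)
    return exp, out


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_variants=400, n_individuals=300, divergence=0.3, seed=42
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_reference_panel(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    return simulate_admixed_cohort(small_panel, small_config)


@pytest.fixture()
def genotypes_from_dosage():
    def _make(dosage, variant_ids=None):
        dosage = np.asarray(dosage)
        n, m = dosage.shape
        if variant_ids is None:
            variant_ids = [f"v{j}" for j in range(m)]
        return GenotypeMatrix(
            individual_ids=np.array([f"i{i}" for i in range(n)], dtype=object),
            variant_ids=np.array(variant_ids, dtype=object),
            dosage=dosage,
            effect_alleles=np.array(["A"] * m, dtype=object),
            other_alleles=np.array(["G"] * m, dtype=object),
        )

    return _make
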