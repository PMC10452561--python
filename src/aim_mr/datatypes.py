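"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* Ancestry proportions live on the **percent scale** (rows sum to 100), so
  every causal effect is "per 1% increase in the proportion of target
  ancestry" — the natural reporting unit for admixture exposures.
* Genotypes are effect-allele dosages 0/1/2 with ``-1`` marking missingness.
* Summary statistics use the fixed column set
  ``variant, effect_allele, other_allele, eaf, beta, se, p, n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUMMARY_STAT_COLUMNS = [
    "variant",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
]


class AimMrError(Exception):
    """Base class for package errors."""


class ConfigurationError(AimMrError):
    """Invalid configuration (dimensions, thresholds, missing fields)."""


class HarmonizationError(AimMrError):
    """Effect alleles cannot be reconciled between two summary-stat sets."""


class EstimatorError(AimMrError):
    """An estimator's preconditions are not met (too few instruments, ...)."""


class SchemaError(AimMrError):
    """An input file does not match its expected schema."""


@dataclass
class AlleleFrequencyTable:
    """Per-variant effect-allele frequencies for K reference populations.

    ``freq`` is a K x M matrix; row order matches ``populations`` and column
    order matches ``variant_ids``.
    """

    variant_ids: np.ndarray
    populations: list[str]
    freq: np.ndarray
    effect_alleles: np.ndarray
    other_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.freq = np.asarray(self.freq, dtype=float)
        self.effect_alleles = np.asarray(self.effect_alleles, dtype=object)
        self.other_alleles = np.asarray(self.other_alleles, dtype=object)
        k, m = self.freq.shape
        if k != len(self.populations):
            raise ConfigurationError(
                f"freq has {k} rows but {len(self.populations)} population labels"
            )
        if m != len(self.variant_ids):
            raise ConfigurationError(
                f"freq has {m} columns but {len(self.variant_ids)} variant ids"
            )
        if k < 2:
            raise ConfigurationError("a reference panel needs at least 2 populations")
        if len(set(self.variant_ids)) != m:
            raise ConfigurationError("duplicated variant ids in panel")
        if np.any(self.freq < 0) or np.any(self.freq > 1):
            raise ConfigurationError("allele frequencies must lie in [0, 1]")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def population_index(self, label: str) -> int:
        try:
            return self.populations.index(label)
        except ValueError:
            raise KeyError(f"unknown population label: {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant": self.variant_ids,
                "effect_allele": self.effect_alleles,
                "other_allele": self.other_alleles,
            }
        )
        for i, pop in enumerate(self.populations):
            df[pop] = self.freq[i]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFrequencyTable":
        fixed = {"variant", "effect_allele", "other_allele"}
        missing = fixed - set(df.columns)
        if missing:
            raise SchemaError(f"panel table missing columns: {sorted(missing)}")
        pops = [c for c in df.columns if c not in fixed]
        return cls(
            variant_ids=df["variant"].to_numpy(),
            populations=pops,
            freq=df[pops].to_numpy(dtype=float).T,
            effect_alleles=df["effect_allele"].to_numpy(),
            other_alleles=df["other_allele"].to_numpy(),
        )


@dataclass
class GenotypeMatrix:
    """Individuals x variants effect-allele dosage matrix (0/1/2, -1 missing)."""

    individual_ids: np.ndarray
    variant_ids: np.ndarray
    dosage: np.ndarray
    effect_alleles: np.ndarray
    other_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosage = np.asarray(self.dosage)
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.variant_ids):
            raise ConfigurationError("dosage shape does not match id vectors")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        idx = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            cols = np.array([idx[v] for v in variant_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"variant absent from genotypes: {exc.args[0]!r}") from None
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            variant_ids=self.variant_ids[cols],
            dosage=self.dosage[:, cols],
            effect_alleles=self.effect_alleles[cols],
            other_alleles=self.other_alleles[cols],
        )


@dataclass
class AncestryProportions:
    """Per-individual ancestry proportions on the percent scale."""

    individual_ids: np.ndarray
    populations: list[str]
    q: np.ndarray  # n x K, percent
    loglik: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.individual_ids), len(self.populations)):
            raise ConfigurationError("q shape does not match ids/populations")
        if np.any(self.q < -1e-9):
            raise ConfigurationError("ancestry proportions must be non-negative")
        sums = self.q.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ConfigurationError("each ancestry row must sum to 100")

    def component(self, label: str) -> np.ndarray:
        return self.q[:, self.populations.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"iid": self.individual_ids})
        for j, pop in enumerate(self.populations):
            df[pop] = self.q[:, j]
        if self.loglik is not None:
            df["loglik"] = self.loglik
        if self.converged is not None:
            df["converged"] = self.converged.astype(int)
        return df


def validate_summary_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Check the fixed summary-statistics schema and value ranges."""
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"summary stats missing column(s): {missing}")
    df = df[SUMMARY_STAT_COLUMNS + [c for c in df.columns if c not in SUMMARY_STAT_COLUMNS]]
    finite_se = np.isfinite(df["se"].to_numpy(dtype=float))
    if np.any(df.loc[finite_se, "se"].to_numpy(dtype=float) <= 0):
        raise SchemaError("summary stats contain non-positive standard errors")
    eaf = df["eaf"].to_numpy(dtype=float)
    ok = np.isnan(eaf) | ((eaf >= 0) & (eaf <= 1))
    if not np.all(ok):
        raise SchemaError("eaf values outside [0, 1]")
    if np.any(df["effect_allele"].to_numpy() == df["other_allele"].to_numpy()):
        raise SchemaError("effect allele equals other allele for some variant")
    return df


@dataclass
class MRResult:
    """Output of a single two-sample MR estimator."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_instruments: int
    cochran_q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    per_instrument: pd.DataFrame | None = None

    def odds_ratio(self) -> tuple[float, float, float]:
        """Exponentiate to (OR, CI low, CI high) for log-odds outcomes."""
        return float(np.exp(self.estimate)), float(np.exp(self.ci_low)), float(
            np.exp(self.ci_high)
        )

    def to_dict(self, exponentiate: bool = False) -> dict:
        if exponentiate:
            est, lo, hi = self.odds_ratio()
        else:
            est, lo, hi = self.estimate, self.ci_low, self.ci_high
        out = {
            "method": self.method,
            "beta_or": est,
            "ci_low": lo,
            "ci_high": hi,
            "beta_p_value": self.p,
            "n_instruments": self.n_instruments,
            "q_p_value": self.q_p,
            "intercept_p_value": self.egger_intercept_p,
        }
        return out
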