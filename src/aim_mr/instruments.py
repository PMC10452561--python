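"""Instrument construction and vetting.

Covers the instrument-selection cascade: per-variant association scans of
the exposure (ancestry proportion, linear model) and outcomes (linear or
logistic), exclusion-list (PheWAS stand-in) filtering, per-variant explained
variance, greedy LD pruning on dosage correlation, Steiger directionality
filtering, and instrument-strength F statistics. Every filter appends a
(stage, threshold, n_in, n_out) record to a provenance log so the cascade
counts reconcile end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datatypes import EstimatorError, GenotypeMatrix

__all__ = [
    "FilterLog",
    "InstrumentSet",
    "ancestry_gwas",
    "outcome_gwas",
    "explained_variance",
    "ld_prune",
    "exclusion_filter",
    "steiger_filter",
    "instrument_strength",
]


@dataclass
class FilterLog:
    """Provenance of a filter cascade: counts must be non-increasing."""

    records: list[dict] = field(default_factory=list)

    def add(self, stage: str, threshold, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage!r} increased the variant count")
        if self.records and self.records[-1]["n_out"] != n_in:
            raise ValueError(
                f"stage {stage!r} input count {n_in} does not match previous "
                f"output count {self.records[-1]['n_out']}"
            )
        self.records.append(
            {"stage": stage, "threshold": threshold, "n_in": n_in, "n_out": n_out}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@dataclass
class InstrumentSet:
    """Retained instruments with explained variance and strength diagnostics."""

    stats: pd.DataFrame
    explained: pd.Series  # per-variant explained variance (standardized scale)
    total_r2: float
    f_statistic: float  # joint F from total_r2
    f_mean_per_instrument: float
    log: FilterLog


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    x = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise EstimatorError("rank-deficient covariate matrix")
    return x


def _stack_covariates(age=None, sex=None, pcs=None):
    parts = []
    for part in (age, sex, pcs):
        if part is not None:
            part = np.asarray(part, dtype=float)
            parts.append(part[:, None] if part.ndim == 1 else part)
    return np.column_stack(parts) if parts else None


def ancestry_gwas(
    genotypes: GenotypeMatrix,
    exposure: np.ndarray,
    age=None,
    sex=None,
    pcs=None,
    n_min: int = 30,
) -> pd.DataFrame:
    """Per-variant OLS association scan of a continuous exposure on dosage.

    The exposure (ancestry percent) is regressed on each variant's dosage
    plus covariates. Covariates are projected out of both exposure and
    dosages once (Frisch-Waugh-Lovell), so the per-variant slope, SE and
    two-sided t-test are exactly the full-model OLS values while the scan
    stays a single matrix operation. Monomorphic variants get beta=0,
    se=inf, p=1 and ``flag='monomorphic'``.
    """
    y = np.asarray(exposure, dtype=float)
    n = len(y)
    if n < n_min:
        raise EstimatorError(f"need at least {n_min} individuals, got {n}")
    g = genotypes.dosage.astype(float)
    if np.any(g < 0):
        g = np.where(g < 0, np.nan, g)
        g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)  # mean-impute missing
    x = _design(_stack_covariates(age, sex, pcs), n)
    q, _ = np.linalg.qr(x)
    y_res = y - q @ (q.T @ y)
    g_res = g - q @ (q.T @ g)

    gss = (g_res**2).sum(axis=0)
    mono = gss <= 1e-12
    gss_safe = np.where(mono, 1.0, gss)
    beta = (g_res * y_res[:, None]).sum(axis=0) / gss_safe
    df = n - x.shape[1] - 1
    rss = (y_res**2).sum() - beta**2 * gss_safe
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / gss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)

    beta[mono] = 0.0
    se[mono] = np.inf
    p[mono] = 1.0

    eaf = g.mean(axis=0) / 2.0
    out = pd.DataFrame(
        {
            "variant": genotypes.variant_ids,
            "effect_allele": genotypes.effect_alleles,
            "other_allele": genotypes.other_alleles,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
            "flag": np.where(mono, "monomorphic", ""),
        }
    )
    return out


def _batched_logistic(
    y: np.ndarray, g: np.ndarray, covariates: np.ndarray | None, max_iter: int = 50
):
    """Newton-Raphson logistic fit of y ~ dosage + covariates for every variant.

    All variants share the covariate block; only the dosage column differs,
    so the fits are batched (one (M, p, p) solve per Newton step). Returns
    (beta, se, converged, separated) for the dosage coefficient. Separation
    is flagged when the dosage coefficient diverges (|beta| > 15) or the fit
    fails to converge.
    """
    n = len(y)
    base = _design(covariates, n)
    p0 = base.shape[1]
    m = g.shape[1]
    # X_v = [dosage_v | base];  parameters (M, p0+1)
    params = np.zeros((m, p0 + 1))
    converged = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        gd = g[:, idx]  # n x ma
        b = params[idx]  # ma x (p0+1)
        eta = gd * b[:, 0] + base @ b[:, 1:].T  # n x ma
        mu = expit(eta)
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        # score vector per variant
        s0 = (gd * resid).sum(axis=0)
        s1 = base.T @ resid  # p0 x ma
        score = np.column_stack([s0, s1.T])  # ma x (p0+1)
        # Hessian blocks
        h00 = (w * gd**2).sum(axis=0)  # ma
        h01 = np.einsum("nm,nm,np->mp", w, gd, base)  # ma x p0
        h11 = np.einsum("nm,np,nq->mpq", w, base, base)  # ma x p0 x p0
        hess = np.empty((idx.size, p0 + 1, p0 + 1))
        hess[:, 0, 0] = h00
        hess[:, 0, 1:] = h01
        hess[:, 1:, 0] = h01
        hess[:, 1:, 1:] = h11
        hess += 1e-10 * np.eye(p0 + 1)
        step = np.linalg.solve(hess, score[:, :, None])[:, :, 0]
        step = np.clip(step, -5.0, 5.0)  # damped for stability
        params[idx] += step
        done = np.max(np.abs(step), axis=1) < 1e-8
        converged[idx[done]] = True
        active[idx[done]] = False

    # standard errors from the final Hessian
    b = params
    eta = g * b[:, 0] + base @ b[:, 1:].T
    mu = expit(eta)
    w = mu * (1.0 - mu)
    h00 = (w * g**2).sum(axis=0)
    h01 = np.einsum("nm,nm,np->mp", w, g, base)
    h11 = np.einsum("nm,np,nq->mpq", w, base, base)
    hess = np.empty((m, p0 + 1, p0 + 1))
    hess[:, 0, 0] = h00
    hess[:, 0, 1:] = h01
    hess[:, 1:, 0] = h01
    hess[:, 1:, 1:] = h11
    hess += 1e-10 * np.eye(p0 + 1)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.maximum(cov[:, 0, 0], 0.0))
    separated = (~converged) | (np.abs(params[:, 0]) > 15.0)
    return params[:, 0], se, converged, separated


def outcome_gwas(
    genotypes: GenotypeMatrix,
    outcome: np.ndarray,
    age=None,
    sex=None,
    pcs=None,
    binary: bool | None = None,
) -> pd.DataFrame:
    """Per-variant association scan of the outcome, additive genotype coding.

    Continuous outcomes use OLS (same machinery as :func:`ancestry_gwas`);
    binary outcomes use maximum-likelihood logistic regression, beta = log OR
    per effect-allele copy, Wald SE and normal p. Variants with (quasi-)
    complete separation are flagged ``'separation'`` and should be excluded
    downstream; monomorphic variants are flagged as in the exposure scan.
    """
    y = np.asarray(outcome, dtype=float)
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    if not binary:
        return outcome_scan_continuous(genotypes, y, age=age, sex=sex, pcs=pcs)
    n = len(y)
    g = genotypes.dosage.astype(float)
    if np.any(g < 0):
        g = np.where(g < 0, np.nan, g)
        g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
    mono = g.var(axis=0) <= 1e-12
    cov = _stack_covariates(age, sex, pcs)
    beta, se, conv, sep = _batched_logistic(y, g, cov)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.inf, se)
    p = np.where(mono, 1.0, p)
    flag = np.where(mono, "monomorphic", np.where(sep, "separation", ""))
    return pd.DataFrame(
        {
            "variant": genotypes.variant_ids,
            "effect_allele": genotypes.effect_alleles,
            "other_allele": genotypes.other_alleles,
            "eaf": g.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
            "flag": flag,
        }
    )


def outcome_scan_continuous(genotypes, y, age=None, sex=None, pcs=None):
    """OLS outcome scan (outcome regressed on dosage + covariates)."""
    return ancestry_gwas(genotypes, y, age=age, sex=sex, pcs=pcs, n_min=10)


def explained_variance(beta: float, maf: float) -> float:
    """Variance in the exposure explained by one variant: beta^2 * 2 * MAF * (1 - MAF).

    ``beta`` must be on the standardized (unit-variance) exposure scale for
    the result to be a variance *proportion*; frequencies above 0.5 should be
    folded to the minor allele before the call.
    """
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"MAF must lie in [0, 0.5] after folding, got {maf}")
    return float(beta**2 * 2.0 * maf * (1.0 - maf))


def explained_variance_series(stats_df: pd.DataFrame, exposure_sd: float) -> pd.Series:
    """Per-variant explained variance with effect sizes standardized by exposure SD."""
    maf = np.minimum(stats_df["eaf"].to_numpy(float), 1.0 - stats_df["eaf"].to_numpy(float))
    beta_std = stats_df["beta"].to_numpy(float) / exposure_sd
    return pd.Series(
        beta_std**2 * 2.0 * maf * (1.0 - maf),
        index=pd.Index(stats_df["variant"], name="variant"),
        name="explained_variance",
    )


def ld_prune(
    genotypes: GenotypeMatrix,
    ranked_variants,
    r2_threshold: float = 0.01,
) -> list:
    """Greedy LD pruning on squared Pearson dosage correlation.

    ``ranked_variants`` must already be ordered by descending priority
    (explained variance); a variant is kept iff its r^2 with every
    previously kept variant is <= the threshold. Deterministic given the
    ranking.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    ranked = list(ranked_variants)
    sub = genotypes.subset_variants(ranked)
    g = sub.dosage.astype(float)
    g = np.where(g < 0, np.nan, g)
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean, g)
    gc = g - g.mean(axis=0)
    sd = gc.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = gc / sd_safe
    corr2 = (z.T @ z / len(z)) ** 2

    kept: list[int] = []
    for i in range(len(ranked)):
        if all(corr2[i, j] <= r2_threshold for j in kept):
            kept.append(i)
    return [ranked[i] for i in kept]


def exclusion_filter(
    stats_df: pd.DataFrame,
    exclusion_list: pd.DataFrame,
    p_threshold: float = 5e-8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop variants with a listed trait association below the p threshold.

    ``exclusion_list`` is the static stand-in for a PheWAS lookup: columns
    ``variant, trait, p``. Returns (retained stats, dropped records).
    """
    if exclusion_list is None or len(exclusion_list) == 0:
        return stats_df, pd.DataFrame(columns=["variant", "trait", "p"])
    hits = exclusion_list[exclusion_list["p"] < p_threshold]
    drop = set(hits["variant"])
    kept = stats_df[~stats_df["variant"].isin(drop)].reset_index(drop=True)
    dropped = hits[hits["variant"].isin(set(stats_df["variant"]))].reset_index(drop=True)
    return kept, dropped


def _r2_from_stats(beta, se, n):
    """Per-variant r^2 from an OLS scan via the t-statistic identity t^2/(t^2+df)."""
    t2 = (np.asarray(beta) / np.asarray(se)) ** 2
    df = np.asarray(n, dtype=float) - 2.0
    return t2 / (t2 + df)


def _r2_binary_observed(lor, eaf, case_fraction):
    """Approximate observed-scale r^2 of a log-OR association.

    Linearises the logistic model around the case fraction c: the per-allele
    change in probability is lor * c(1-c), so the explained variance on the
    observed 0/1 scale (variance c(1-c)) is approximately
    lor^2 * c(1-c) * 2 f (1-f). A documented approximation, adequate for the
    directionality comparison it feeds.
    """
    c = case_fraction
    f = np.asarray(eaf, dtype=float)
    return np.asarray(lor) ** 2 * c * (1.0 - c) * 2.0 * f * (1.0 - f)


def steiger_filter(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    outcome_binary: bool,
    case_fraction: float | None = None,
) -> tuple[list, pd.DataFrame]:
    """Directionality filter: keep instruments explaining more exposure than outcome variance.

    Variants whose outcome r^2 exceeds their exposure r^2 are dropped
    (possible reverse causation). Variants with missing EAF on the binary
    side cannot be scored; they are retained with a warning flag. Returns
    (retained variant list, per-variant diagnostic table).
    """
    exp = exposure_stats.set_index("variant")
    out = outcome_stats.set_index("variant")
    shared = exp.index.intersection(out.index)
    exp, out = exp.loc[shared], out.loc[shared]
    r2_exp = _r2_from_stats(exp["beta"], exp["se"], exp["n"])
    if outcome_binary:
        if case_fraction is None:
            raise ValueError("case_fraction required for a binary outcome")
        eaf = out["eaf"].to_numpy(float)
        missing = ~np.isfinite(eaf)
        r2_out = _r2_binary_observed(out["beta"].to_numpy(float), np.where(missing, 0.5, eaf), case_fraction)
    else:
        r2_out = _r2_from_stats(out["beta"], out["se"], out["n"])
        missing = np.zeros(len(shared), dtype=bool)
    keep = (r2_exp > r2_out) | missing
    diag = pd.DataFrame(
        {
            "variant": shared,
            "r2_exposure": r2_exp,
            "r2_outcome": r2_out,
            "retained": keep,
            "flag": np.where(missing, "missing_eaf_retained", ""),
        }
    )
    return list(shared[keep]), diag


def instrument_strength(total_r2: float, n: int, k: int) -> float:
    """Joint instrument-strength F statistic from the total explained variance.

    F = (R^2 / (1 - R^2)) * ((n - k - 1) / k) for k instruments fitted to n
    exposure-sample individuals.
    """
    if not (0.0 <= total_r2 < 1.0):
        raise ValueError("total_r2 must lie in [0, 1)")
    if n <= k + 1 or k < 1:
        raise ValueError("need n > k + 1 >= 2")
    return float(total_r2 / (1.0 - total_r2) * (n - k - 1) / k)


def mean_f_statistic(stats_df: pd.DataFrame) -> float:
    """Mean per-instrument F: average of squared per-variant t statistics."""
    b = stats_df["beta"].to_numpy(float)
    s = stats_df["se"].to_numpy(float)
    ok = np.isfinite(s) & (s > 0)
    return float(np.mean((b[ok] / s[ok]) ** 2))
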