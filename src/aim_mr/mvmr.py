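"""Multivariable Mendelian randomization: joint direct effects of several exposures.

With per-instrument betas for k exposures and one outcome, harmonized to a
common effect allele, the direct effects solve a weighted least-squares fit
of the outcome betas on the exposure-beta matrix without intercept, weights
1/se_outcome^2 (first-order). Diagnostics: a heterogeneity Q on L - k
degrees of freedom and a Sanderson-style conditional F statistic per
exposure, measuring instrument strength for that exposure given the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EstimatorError

__all__ = ["MVMRInput", "MVMRResult", "mvmr_fit", "conditional_f", "mvmr_q"]


@dataclass
class MVMRInput:
    """Harmonized instrument-level data for k exposures and one outcome."""

    variants: np.ndarray
    beta_exposures: np.ndarray  # L x k
    se_exposures: np.ndarray  # L x k
    beta_outcome: np.ndarray  # L
    se_outcome: np.ndarray  # L
    exposure_names: list[str]

    def __post_init__(self) -> None:
        self.beta_exposures = np.atleast_2d(np.asarray(self.beta_exposures, float))
        if self.beta_exposures.shape[0] == 1 and len(self.beta_outcome) > 1:
            self.beta_exposures = self.beta_exposures.T
        self.se_exposures = np.atleast_2d(np.asarray(self.se_exposures, float))
        if self.se_exposures.shape[0] == 1 and len(self.beta_outcome) > 1:
            self.se_exposures = self.se_exposures.T
        self.beta_outcome = np.asarray(self.beta_outcome, float)
        self.se_outcome = np.asarray(self.se_outcome, float)
        L, k = self.beta_exposures.shape
        if L < k + 2:
            raise EstimatorError(f"need at least k+2={k + 2} instruments, got {L}")
        for arr in (self.beta_exposures, self.se_exposures, self.beta_outcome, self.se_outcome):
            if np.any(~np.isfinite(arr)):
                raise EstimatorError("MVMR input contains missing or non-finite entries")

    @property
    def n_instruments(self) -> int:
        return self.beta_exposures.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.beta_exposures.shape[1]


@dataclass
class MVMRResult:
    exposure_names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    p: np.ndarray
    conditional_f: np.ndarray
    weak: np.ndarray  # conditional F < 10
    q: float
    q_df: int
    q_p: float

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.estimates)

    def to_dict(self) -> dict:
        out = {}
        for j, name in enumerate(self.exposure_names):
            out[name] = {
                "beta": float(self.estimates[j]),
                "or": float(np.exp(self.estimates[j])),
                "se": float(self.se[j]),
                "p": float(self.p[j]),
                "conditional_f": float(self.conditional_f[j]),
                "weak_instruments": bool(self.weak[j]),
            }
        out["q"] = self.q
        out["q_df"] = self.q_df
        out["q_p"] = self.q_p
        return out


def mvmr_fit(inp: MVMRInput) -> MVMRResult:
    """Direct effects by WLS of outcome betas on the exposure-beta matrix.

    No intercept; weights 1/se_outcome^2; normal p-values. Collinear
    exposure columns (condition number > 1e8) abort with an error naming
    the problem rather than returning unstable estimates.
    """
    X_full = inp.beta_exposures
    y = inp.beta_outcome
    w = 1.0 / inp.se_outcome**2
    # an all-zero exposure column carries no instrument signal: drop it with
    # a warning so the fit reduces to the nested model (its direct effect is
    # reported as NaN)
    zero_cols = np.max(np.abs(X_full), axis=0) == 0.0
    if zero_cols.all():
        raise EstimatorError("all exposure beta columns are zero")
    if zero_cols.any():
        import warnings

        dropped = [n for n, z in zip(inp.exposure_names, zero_cols) if z]
        warnings.warn(
            f"exposure(s) {dropped} have all-zero betas; fitting the nested "
            "model without them",
            stacklevel=2,
        )
    X = X_full[:, ~zero_cols]
    cond = np.linalg.cond(np.sqrt(w)[:, None] * X)
    if cond > 1e8:
        raise EstimatorError(
            f"exposure beta columns are collinear (condition number {cond:.2e}); "
            "direct effects are not identified"
        )
    xtwx = X.T @ (w[:, None] * X)
    theta_fit = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ theta_fit
    q = float(np.sum(w * resid**2))
    L = X.shape[0]
    k_total = X_full.shape[1]
    df = L - X.shape[1]
    sigma2 = max(1.0, q / df)  # multiplicative random effects, as univariable IVW
    cov = sigma2 * np.linalg.inv(xtwx)
    se_fit = np.sqrt(np.diag(cov))
    theta = np.full(k_total, np.nan)
    se = np.full(k_total, np.nan)
    theta[~zero_cols] = theta_fit
    se[~zero_cols] = se_fit
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(theta / se))
    f = conditional_f(inp)
    return MVMRResult(
        exposure_names=list(inp.exposure_names),
        estimates=theta,
        se=se,
        p=p,
        conditional_f=f,
        weak=f < 10.0,
        q=q,
        q_df=df,
        q_p=float(stats.chi2.sf(q, df)),
    )


def conditional_f(inp: MVMRInput) -> np.ndarray:
    """Conditional instrument-strength F per exposure.

    For exposure j, its betas are regressed on the other exposures' betas
    (no intercept, weights 1/se_xj^2); the weighted residual sum of squares
    Q_xj measures the instrument signal left after conditioning, and
    F_j = Q_xj / (L - k + 1). With a single exposure this reduces to the
    mean per-instrument F (mean squared t statistic); duplicated exposure
    columns give F near 0. Values below 10 conventionally flag weak
    instruments.
    """
    X = inp.beta_exposures
    L, k = X.shape
    f = np.empty(k)
    for j in range(k):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        w = 1.0 / inp.se_exposures[:, j] ** 2
        if others.shape[1] == 0:
            resid = xj
        else:
            xtwx = others.T @ (w[:, None] * others)
            coef = np.linalg.lstsq(xtwx, others.T @ (w * xj), rcond=None)[0]
            resid = xj - others @ coef
        q_x = float(np.sum(w * resid**2))
        f[j] = q_x / (L - k + 1)
    return f


def mvmr_q(inp: MVMRInput, estimates: np.ndarray) -> tuple[float, int, float]:
    """Heterogeneity Q at given direct-effect estimates; chi-square on L-k df."""
    w = 1.0 / inp.se_outcome**2
    resid = inp.beta_outcome - inp.beta_exposures @ np.asarray(estimates, float)
    q = float(np.sum(w * resid**2))
    df = inp.n_instruments - inp.n_exposures
    return q, df, float(stats.chi2.sf(q, df))


def build_mvmr_input(
    exposure_stats: list[pd.DataFrame],
    outcome_stats: pd.DataFrame,
    exposure_names: list[str],
) -> MVMRInput:
    """Assemble an MVMRInput from harmonized per-exposure summary statistics.

    All inputs must already share effect-allele orientation (run
    :func:`aim_mr.mr.harmonize` of each exposure against the outcome first);
    only variants present in every table are used.
    """
    idx = outcome_stats.set_index("variant").index
    for ex in exposure_stats:
        idx = idx.intersection(ex.set_index("variant").index)
    out = outcome_stats.set_index("variant").loc[idx]
    bx = np.column_stack(
        [ex.set_index("variant").loc[idx, "beta"].to_numpy(float) for ex in exposure_stats]
    )
    sx = np.column_stack(
        [ex.set_index("variant").loc[idx, "se"].to_numpy(float) for ex in exposure_stats]
    )
    return MVMRInput(
        variants=np.asarray(idx),
        beta_exposures=bx,
        se_exposures=sx,
        beta_outcome=out["beta"].to_numpy(float),
        se_outcome=out["se"].to_numpy(float),
        exposure_names=exposure_names,
    )
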