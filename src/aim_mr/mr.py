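"""Two-sample Mendelian randomization estimators, implemented from closed forms.

Per-instrument Wald ratios r_i = beta_outcome_i / beta_exposure_i with
first-order standard errors se_i = se_outcome_i / |beta_exposure_i| feed:

* **IVW** — inverse-variance weighted mean of the ratios, equivalently a
  weighted least-squares fit through the origin of outcome on exposure betas
  with weights 1/se_outcome^2; multiplicative random-effects standard error
  (inflation by sqrt(max(1, Q / (L - 1)))), normal p-value.
* **Cochran's Q** — heterogeneity with first-order weights, chi-square on
  L - 1 degrees of freedom; a pleiotropy proxy.
* **MR-Egger** — weighted regression with an intercept after orienting all
  exposure betas positive; the intercept and its p-value flag directional
  horizontal pleiotropy; t-based inference on L - 2 df, multiplicative
  random effects.
* **Weighted median** — cumulative-weight interpolation at 50%, robust to up
  to 50% invalid weight; SE by seeded parametric bootstrap.
* **Radial MR** — the same IVW fit in radial coordinates, exposing per-
  instrument Q contributions for outlier flagging (chi-square(1) test),
  single-pass removal and refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EstimatorError, HarmonizationError, MRResult

__all__ = [
    "HarmonizedSet",
    "RadialResult",
    "harmonize",
    "ivw",
    "cochran_q",
    "egger",
    "weighted_median",
    "radial_filter",
    "scatter_funnel_data",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(str(a1).upper()) == str(a2).upper()


@dataclass
class HarmonizedSet:
    """Instrument-level exposure/outcome betas aligned to a common effect allele."""

    data: pd.DataFrame  # variant, beta_exposure, se_exposure, beta_outcome,
    # se_outcome, eaf_exposure, eaf_outcome, action
    audit: pd.DataFrame  # every input variant with the action taken

    @property
    def n_instruments(self) -> int:
        return len(self.data)

    def ratios(self) -> tuple[np.ndarray, np.ndarray]:
        """First-order Wald ratios and their standard errors.

        Instruments with a zero exposure beta are excluded by
        :func:`harmonize`, so the division is safe here.
        """
        bx = self.data["beta_exposure"].to_numpy(float)
        by = self.data["beta_outcome"].to_numpy(float)
        sy = self.data["se_outcome"].to_numpy(float)
        return by / bx, sy / np.abs(bx)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_policy: str = "drop",
    maf_window: float = 0.3,
) -> HarmonizedSet:
    """Align outcome records to the exposure's effect alleles.

    Matching alleles are kept as-is; swapped alleles flip the outcome beta
    sign and complement the EAF; incompatible allele pairs are removed.
    Palindromic (A/T, C/G) variants cannot be strand-resolved from alleles
    alone: policy ``'drop'`` removes them all, ``'maf'`` retains those whose
    EAF is below ``maf_window`` on both sides (frequency resolves the
    strand), ``'keep'`` retains everything. Instruments with beta_exposure
    exactly 0 are removed (their Wald ratio is undefined). Every decision is
    recorded in the audit table.
    """
    if palindromic_policy not in {"drop", "maf", "keep"}:
        raise ValueError(f"unknown palindromic policy: {palindromic_policy!r}")
    exp = exposure.set_index("variant")
    out = outcome.set_index("variant")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise HarmonizationError("no shared variants between exposure and outcome")

    rows, audit = [], []
    for v in shared:
        e, o = exp.loc[v], out.loc[v]
        ea_e, oa_e = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        ea_o, oa_o = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        beta_o, eaf_o = float(o["beta"]), float(o["eaf"])
        if (ea_o, oa_o) == (ea_e, oa_e):
            action = "kept"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_o, eaf_o = -beta_o, 1.0 - eaf_o
            action = "flipped"
        else:
            audit.append({"variant": v, "action": "removed-incompatible"})
            continue
        if _is_palindromic(ea_e, oa_e):
            if palindromic_policy == "drop":
                audit.append({"variant": v, "action": "removed-palindromic"})
                continue
            if palindromic_policy == "maf":
                mafs = [min(float(e["eaf"]), 1 - float(e["eaf"])), min(eaf_o, 1 - eaf_o)]
                if any(m >= maf_window for m in mafs):
                    audit.append({"variant": v, "action": "removed-palindromic"})
                    continue
        if float(e["beta"]) == 0.0:
            audit.append({"variant": v, "action": "removed-zero-exposure-beta"})
            continue
        audit.append({"variant": v, "action": action})
        rows.append(
            {
                "variant": v,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "beta_exposure": float(e["beta"]),
                "se_exposure": float(e["se"]),
                "eaf_exposure": float(e["eaf"]),
                "beta_outcome": beta_o,
                "se_outcome": float(o["se"]),
                "eaf_outcome": eaf_o,
                "action": action,
            }
        )
    return HarmonizedSet(
        data=pd.DataFrame(rows), audit=pd.DataFrame(audit, columns=["variant", "action"])
    )


def _ivw_core(r: np.ndarray, s: np.ndarray):
    w = 1.0 / s**2
    est = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - est) ** 2))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    return est, q, se_fixed


def ivw(h: HarmonizedSet, allow_single: bool = False) -> MRResult:
    """Random-effects IVW estimate with first-order weights.

    The point estimate equals WLS-through-origin of outcome on exposure
    betas with weights 1/se_outcome^2. The fixed-effect SE is inflated by
    sqrt(max(1, Q/(L-1))) (multiplicative random effects), which keeps the
    type I error controlled under the causal null; p from the normal.
    """
    r, s = h.ratios()
    L = len(r)
    if L < 2 and not allow_single:
        raise EstimatorError(f"IVW needs at least 2 instruments, got {L}")
    est, q, se_fixed = _ivw_core(r, s)
    if L > 1:
        infl = float(np.sqrt(max(1.0, q / (L - 1))))
        q_df = L - 1
        q_p = float(stats.chi2.sf(q, q_df))
    else:
        infl, q_df, q_p = 1.0, 0, float("nan")
    se = se_fixed * infl
    z = est / se
    return MRResult(
        method="ivw",
        estimate=est,
        se=se,
        ci_low=est - 1.959963984540054 * se,
        ci_high=est + 1.959963984540054 * se,
        p=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=L,
        cochran_q=q,
        q_df=q_df,
        q_p=q_p,
        per_instrument=pd.DataFrame(
            {"variant": h.data["variant"], "ratio": r, "se": s, "weight": 1.0 / s**2}
        ),
    )


def cochran_q(h: HarmonizedSet, estimate: float) -> tuple[float, int, float]:
    """Cochran's Q at a given pooled estimate, first-order weights, chi2(L-1) p."""
    r, s = h.ratios()
    w = 1.0 / s**2
    q = float(np.sum(w * (r - estimate) ** 2))
    df = len(r) - 1
    return q, df, float(stats.chi2.sf(q, df)) if df > 0 else 1.0


def egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger regression: weighted fit with an intercept for directional pleiotropy.

    Exposure betas are oriented positive (outcome betas sign-adjusted), then
    beta_outcome is regressed on beta_exposure with weights 1/se_outcome^2.
    The slope is the causal estimate and the intercept the average
    directional pleiotropy; t inference on L-2 df with multiplicative
    random-effects inflation sqrt(max(1, Q_egger/(L-2))).
    """
    L = h.n_instruments
    if L < 3:
        raise EstimatorError(f"MR-Egger needs at least 3 instruments, got {L}")
    bx = h.data["beta_exposure"].to_numpy(float)
    by = h.data["beta_outcome"].to_numpy(float)
    sy = h.data["se_outcome"].to_numpy(float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(L), bx])
    xtwx = x.T @ (w[:, None] * x)
    coef = np.linalg.solve(xtwx, x.T @ (w * by))
    resid = by - x @ coef
    q = float(np.sum(w * resid**2))
    df = L - 2
    sigma2 = max(1.0, q / df)  # multiplicative random effects
    cov = sigma2 * np.linalg.inv(xtwx)
    se_int, se_slope = np.sqrt(np.diag(cov))
    t_slope = coef[1] / se_slope
    t_int = coef[0] / se_int
    tq = stats.t.ppf(0.975, df)
    return MRResult(
        method="egger",
        estimate=float(coef[1]),
        se=float(se_slope),
        ci_low=float(coef[1] - tq * se_slope),
        ci_high=float(coef[1] + tq * se_slope),
        p=float(2.0 * stats.t.sf(abs(t_slope), df)),
        n_instruments=L,
        cochran_q=q,
        q_df=df,
        q_p=float(stats.chi2.sf(q, df)),
        egger_intercept=float(coef[0]),
        egger_intercept_se=float(se_int),
        egger_intercept_p=float(2.0 * stats.t.sf(abs(t_int), df)),
    )


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="mergesort")
    r_s, w_s = r[order], w[order]
    w_s = w_s / w_s.sum()
    cum = np.cumsum(w_s) - 0.5 * w_s  # mid-point cumulative weight
    below = np.flatnonzero(cum < 0.5)
    if len(below) == 0:
        return float(r_s[0])
    i = below[-1]
    if i == len(r_s) - 1:
        return float(r_s[-1])
    # linear interpolation between bracketing order statistics
    return float(
        r_s[i] + (r_s[i + 1] - r_s[i]) * (0.5 - cum[i]) / (cum[i + 1] - cum[i])
    )


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted median of the Wald ratios with inverse-variance weights.

    Consistent when at least half the weight comes from valid instruments.
    SE from a seeded parametric bootstrap: each resample redraws every
    instrument's exposure and outcome betas from their normal distributions
    and recomputes the weighted median.
    """
    L = h.n_instruments
    if L < 3:
        raise EstimatorError(f"weighted median needs at least 3 instruments, got {L}")
    if n_boot < 100:
        import warnings

        warnings.warn("n_boot < 100 gives unstable bootstrap SEs", stacklevel=2)
    r, s = h.ratios()
    w = 1.0 / s**2
    est = _weighted_median_point(r, w)

    rng = np.random.default_rng(seed)
    bx = h.data["beta_exposure"].to_numpy(float)
    sx = h.data["se_exposure"].to_numpy(float)
    by = h.data["beta_outcome"].to_numpy(float)
    sy = h.data["se_outcome"].to_numpy(float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        r_b = by_b / bx_b
        s_b = sy / np.abs(bx_b)
        boots[b] = _weighted_median_point(r_b, 1.0 / s_b**2)
    se = float(boots.std(ddof=1))
    z = est / se if se > 0 else np.inf
    return MRResult(
        method="weighted_median",
        estimate=est,
        se=se,
        ci_low=est - 1.959963984540054 * se,
        ci_high=est + 1.959963984540054 * se,
        p=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=L,
    )


@dataclass
class RadialResult:
    """Per-instrument Q decomposition and the post-exclusion instrument list."""

    table: pd.DataFrame  # variant, ratio, weight, q_i, outlier
    estimate_initial: float
    estimate_refit: float
    global_q: float
    alpha: float
    retained: list


def radial_filter(h: HarmonizedSet, alpha: float = 0.05) -> RadialResult:
    """Radial MR outlier detection with first-order weights, single-pass removal.

    The radial IVW fit (regression of r_i*sqrt(w_i) on sqrt(w_i) through the
    origin) coincides with standard IVW; each instrument contributes
    Q_i = w_i (r_i - estimate)^2 and the Q_i sum exactly to the global Q.
    Instruments with a chi-square(1) p below ``alpha`` are flagged and the
    model is refit once without them.
    """
    if h.n_instruments < 3:
        raise EstimatorError("radial MR needs at least 3 instruments")
    r, s = h.ratios()
    w = 1.0 / s**2
    est, q, _ = _ivw_core(r, s)
    q_i = w * (r - est) ** 2
    cutoff = stats.chi2.ppf(1.0 - alpha, 1)
    outlier = q_i > cutoff
    keep = ~outlier
    if keep.sum() >= 2:
        est_refit, _, _ = _ivw_core(r[keep], s[keep])
    else:
        est_refit = est
    variants = h.data["variant"].to_numpy()
    table = pd.DataFrame(
        {
            "variant": variants,
            "ratio": r,
            "weight": w,
            "q_i": q_i,
            "q_p": stats.chi2.sf(q_i, 1),
            "outlier": outlier,
        }
    )
    return RadialResult(
        table=table,
        estimate_initial=est,
        estimate_refit=est_refit,
        global_q=q,
        alpha=alpha,
        retained=list(variants[keep]),
    )


def subset_harmonized(h: HarmonizedSet, variants) -> HarmonizedSet:
    """Restrict a harmonized set to the given variants (order preserved)."""
    keep = h.data["variant"].isin(set(variants))
    return HarmonizedSet(data=h.data[keep].reset_index(drop=True), audit=h.audit)


def scatter_funnel_data(
    h: HarmonizedSet, results: list[MRResult]
) -> dict[str, pd.DataFrame]:
    """Plot-ready tables for the scatter and funnel diagnostics.

    ``scatter``: per-instrument exposure/outcome betas with SE bars plus one
    fitted line (slope, intercept) per estimator. ``funnel``: per-instrument
    Wald ratio against precision 1/se with each estimator's vertical line.
    """
    if h.n_instruments == 0:
        raise EstimatorError("cannot build plot data from an empty instrument set")
    r, s = h.ratios()
    scatter = h.data[
        ["variant", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]
    ].copy()
    lines = pd.DataFrame(
        {
            "method": [res.method for res in results],
            "slope": [res.estimate for res in results],
            "intercept": [res.egger_intercept or 0.0 for res in results],
        }
    )
    funnel = pd.DataFrame(
        {"variant": h.data["variant"], "ratio": r, "precision": 1.0 / s}
    )
    return {"scatter": scatter, "scatter_lines": lines, "funnel": funnel}
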