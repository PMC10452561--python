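"""Genotype principal components for stratification sensitivity analyses.

Eigenstrat normalization: each variant column is centred by twice its sample
allele frequency and scaled by sqrt(2 p (1 - p)), then a truncated SVD gives
per-individual scores and per-variant loadings. In an admixed sample the
leading components track the major ancestry gradients, so adjusting a GWAS
for an ancestry-correlated component removes the very signal an
ancestry-proportion exposure relies on — the point of the sensitivity
analysis this module feeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EstimatorError, GenotypeMatrix

__all__ = ["PCResult", "genotype_pca", "ancestry_correlated_pc"]


@dataclass
class PCResult:
    individual_ids: np.ndarray
    variant_ids: np.ndarray
    scores: np.ndarray  # n x n_pcs
    loadings: np.ndarray  # m x n_pcs
    variance_fraction: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"iid": self.individual_ids})
        for j in range(self.scores.shape[1]):
            df[f"PC{j + 1}"] = self.scores[:, j]
        return df


def genotype_pca(
    genotypes: GenotypeMatrix, n_pcs: int = 10, maf_min: float = 0.01
) -> PCResult:
    """Eigenstrat-normalized genotype PCA via truncated SVD.

    Variants below the MAF floor or entirely missing are dropped. Sign
    convention: each component is oriented so its largest-|loading| variant
    has a positive loading, making the decomposition deterministic.
    """
    n = genotypes.n_individuals
    if n < n_pcs + 1:
        raise EstimatorError(f"need at least {n_pcs + 1} individuals for {n_pcs} PCs")
    g = genotypes.dosage.astype(float)
    g = np.where(g < 0, np.nan, g)
    all_missing = np.all(np.isnan(g), axis=0)
    g = g[:, ~all_missing]
    variant_ids = genotypes.variant_ids[~all_missing]
    p_hat = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p_hat, 1.0 - p_hat)
    keep = maf >= maf_min
    g, p_hat, variant_ids = g[:, keep], p_hat[keep], variant_ids[keep]
    if g.shape[1] == 0:
        raise EstimatorError("no variants left after the MAF filter")
    g = np.where(np.isnan(g), 2.0 * p_hat, g)  # mean-impute residual missingness
    z = (g - 2.0 * p_hat) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    total_var = float((z**2).sum()) / (n - 1)
    if total_var <= 1e-12:
        raise EstimatorError("zero genetic variance: individuals are identical")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    scores = u[:, :n_pcs] * s[:n_pcs]
    loadings = vt[:n_pcs].T
    # deterministic sign: largest-|loading| variant positive per component
    for j in range(n_pcs):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    var_frac = (s[:n_pcs] ** 2 / (n - 1)) / total_var
    return PCResult(
        individual_ids=genotypes.individual_ids,
        variant_ids=variant_ids,
        scores=scores,
        loadings=loadings,
        variance_fraction=var_frac,
    )


def ancestry_correlated_pc(pcs: PCResult, exposure: np.ndarray) -> int:
    """1-based index of the component most correlated (|r|) with the exposure.

    This is the component the leave-one-out sensitivity analysis removes
    from the adjustment set (in the admixed-Chilean setting it is the second
    component, which separates the two indigenous ancestries).
    """
    y = np.asarray(exposure, float)
    corrs = [
        abs(np.corrcoef(pcs.scores[:, j], y)[0, 1]) for j in range(pcs.scores.shape[1])
    ]
    return int(np.argmax(corrs)) + 1


def pc_adjustment_matrix(pcs: PCResult, mode: str, exposure: np.ndarray | None = None):
    """Covariate block for PC-adjusted GWAS.

    mode ``'none'`` returns None (unadjusted); ``'all'`` returns all
    components; ``'drop_ancestry_pc'`` returns all components except the one
    most correlated with the exposure (which must be supplied).
    """
    if mode == "none":
        return None, None
    if mode == "all":
        return pcs.scores, None
    if mode == "drop_ancestry_pc":
        if exposure is None:
            raise ValueError("exposure required to identify the ancestry PC")
        j = ancestry_correlated_pc(pcs, exposure)
        keep = [c for c in range(pcs.scores.shape[1]) if c != j - 1]
        return pcs.scores[:, keep], j
    raise ValueError(f"unknown PC adjustment mode: {mode!r}")
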