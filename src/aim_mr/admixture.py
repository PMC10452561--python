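"""Supervised ancestry-proportion estimation by maximum likelihood.

Given fixed reference-panel allele frequencies ``p_km``, each individual's
ancestry vector q (on the K-simplex) maximises the binomial log-likelihood

    l(q) = sum_m [ g_m ln f_m + (2 - g_m) ln(1 - f_m) ],   f_m = sum_k q_k p_km

over observed genotypes g_m in {0,1,2} (missing genotypes are dropped from
the sum). The maximiser is found with the standard supervised-admixture EM
fixed point

    q_k <- q_k / (2 M) * sum_m [ g_m p_km / f_m + (2 - g_m)(1 - p_km) / (1 - f_m) ]

which stays on the simplex and increases the likelihood monotonically. This
is the same model the ADMIXTURE software fits in supervised mode; estimates
are validated by recovery on simulated data, not by byte-comparison to that
software (which uses different acceleration internals).
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    AlleleFrequencyTable,
    AncestryProportions,
    ConfigurationError,
    GenotypeMatrix,
)

PANEL_CLAMP = (1e-3, 1.0 - 1e-3)


def estimate_proportions(
    genotypes: GenotypeMatrix,
    panel: AlleleFrequencyTable,
    tol: float = 1e-6,
    max_iter: int = 2000,
    check_monotone: bool = True,
) -> AncestryProportions:
    """Supervised EM estimate of individual ancestry proportions (percent scale).

    Genotype variants must be a subset of panel variants; effect alleles that
    disagree with the panel but match after swapping are flipped (dosage
    2 - g). Collinear reference populations (identical frequency vectors)
    make individual components non-identifiable; a warning is emitted and
    only the *sum* of the collinear components is meaningful.
    """
    pos = {v: j for j, v in enumerate(panel.variant_ids)}
    missing = [v for v in genotypes.variant_ids if v not in pos]
    if len(missing) == len(genotypes.variant_ids):
        raise ConfigurationError("no overlapping variants between genotypes and panel")
    keep = [i for i, v in enumerate(genotypes.variant_ids) if v in pos]
    cols = np.array([pos[genotypes.variant_ids[i]] for i in keep], dtype=int)

    p = np.clip(panel.freq[:, cols], *PANEL_CLAMP)  # K x M
    g = genotypes.dosage[:, keep].astype(float)  # n x M, -1 = missing

    # harmonize alleles: flip dosage where effect/other are swapped
    ge = genotypes.effect_alleles[keep]
    go = genotypes.other_alleles[keep]
    pe = panel.effect_alleles[cols]
    po = panel.other_alleles[cols]
    same = (ge == pe) & (go == po)
    swapped = (ge == po) & (go == pe)
    bad = ~(same | swapped)
    if np.any(bad):
        raise ConfigurationError(
            f"{int(bad.sum())} variants have alleles incompatible with the panel"
        )
    if np.any(swapped):
        obs = g[:, swapped] >= 0
        g[:, swapped] = np.where(obs, 2.0 - g[:, swapped], g[:, swapped])

    # flag non-identifiable (near-duplicate) reference populations
    k = p.shape[0]
    for a in range(k):
        for b in range(a + 1, k):
            if np.allclose(p[a], p[b], atol=1e-12):
                warnings.warn(
                    f"reference populations {panel.populations[a]!r} and "
                    f"{panel.populations[b]!r} have identical frequencies; their "
                    "individual ancestry components are not identifiable",
                    stacklevel=2,
                )

    observed = g >= 0
    gobs = np.where(observed, g, 0.0)
    two_minus = np.where(observed, 2.0 - g, 0.0)
    m_obs = observed.sum(axis=1).astype(float)  # per-individual observed count
    if np.any(m_obs == 0):
        raise ConfigurationError("some individuals have no observed genotypes")

    n = g.shape[0]
    q = np.full((n, k), 1.0 / k)  # uniform simplex start

    def loglik(qm: np.ndarray) -> np.ndarray:
        f = qm @ p
        return (gobs * np.log(f) + two_minus * np.log1p(-f)).sum(axis=1)

    ll = loglik(q)
    converged = np.zeros(n, dtype=bool)
    active = np.arange(n)
    for _ in range(max_iter):
        qa = q[active]
        f = qa @ p  # n_active x M
        a = gobs[active] / f
        b = two_minus[active] / (1.0 - f)
        num = a @ p.T + b @ (1.0 - p).T  # n_active x K
        q_new = qa * num / (2.0 * m_obs[active, None])
        q_new /= q_new.sum(axis=1, keepdims=True)
        ll_new = (
            gobs[active] * np.log(q_new @ p)
            + two_minus[active] * np.log1p(-(q_new @ p))
        ).sum(axis=1)
        if check_monotone and np.any(ll_new < ll[active] - 1e-8 * np.abs(ll[active])):
            raise RuntimeError("EM log-likelihood decreased; numerical failure")
        gain = ll_new - ll[active]
        q[active], ll[active] = q_new, ll_new
        done = gain < tol
        converged[active[done]] = True
        active = active[~done]  # converged individuals are frozen
        if active.size == 0:
            break

    q_pct = 100.0 * q
    q_pct *= 100.0 / q_pct.sum(axis=1, keepdims=True)
    return AncestryProportions(
        individual_ids=genotypes.individual_ids,
        populations=list(panel.populations),
        q=q_pct,
        loglik=ll,
        converged=converged,
    )
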