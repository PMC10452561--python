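"""Informativeness for assignment (I_n) and ancestry-informative marker preselection.

For a biallelic marker with effect-allele frequency ``p_i`` in each of K
populations, Rosenberg's informativeness for assignment is

    I_n = sum_j [ -p_j ln p_j ] + sum_i sum_j (p_ij / K) ln p_ij

where j runs over the two alleles (frequencies p and 1-p), and p_j is the
unweighted mean of p_ij over the K populations. I_n is measured in nats,
is zero iff all populations share a frequency, and attains ln K at a fixed
difference. The 0*ln(0) terms are taken as 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AlleleFrequencyTable

__all__ = ["compute_in", "compute_in_table", "preselect_markers"]


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x * ln x with the 0*ln0 = 0 convention."""
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def compute_in(freqs_by_pop) -> float:
    """I_n of one biallelic variant given per-population effect-allele frequencies.

    Parameters
    ----------
    freqs_by_pop:
        Length-K array of effect-allele frequencies, one per population.

    Returns
    -------
    float
        I_n in nats, in [0, ln K].
    """
    p = np.asarray(freqs_by_pop, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need frequencies for at least two populations")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return float(_in_vectorized(p[:, None])[0])


def _in_vectorized(freq: np.ndarray) -> np.ndarray:
    """I_n for each column of a K x M frequency matrix."""
    k = freq.shape[0]
    pbar = freq.mean(axis=0)  # unweighted average over populations
    entropy = -(_xlogx(pbar) + _xlogx(1.0 - pbar))
    within = (_xlogx(freq) + _xlogx(1.0 - freq)).sum(axis=0) / k
    i_n = entropy + within
    # clip tiny negative round-off
    return np.where(i_n < 0, 0.0, i_n)


def compute_in_table(
    panel: AlleleFrequencyTable, populations: list[str]
) -> pd.DataFrame:
    """I_n of every panel variant for one comparison (subset of populations)."""
    rows = [panel.population_index(p) for p in populations]
    i_n = _in_vectorized(panel.freq[rows])
    return pd.DataFrame(
        {
            "variant": panel.variant_ids,
            "comparison": "-".join(populations),
            "i_n": i_n,
        }
    )


def preselect_markers(
    panel: AlleleFrequencyTable,
    target: str,
    comparisons: list[str],
    top_k: int,
) -> tuple[list, dict[str, pd.DataFrame]]:
    """Preselect candidate ancestry-informative markers.

    Runs one pairwise K=2 comparison of the target population against each
    population in ``comparisons``, ranks variants by I_n (descending; ties
    broken by variant id so the ranking is deterministic), takes the top
    ``top_k`` of each comparison and returns the union, sorted by variant id,
    together with the per-comparison ranked tables.
    """
    if top_k > panel.n_variants:
        raise ValueError(
            f"top_k={top_k} exceeds the {panel.n_variants} panel variants"
        )
    panel.population_index(target)  # raises KeyError on unknown label
    union: set = set()
    tables: dict[str, pd.DataFrame] = {}
    for other in comparisons:
        table = compute_in_table(panel, [target, other])
        table = table.sort_values(
            ["i_n", "variant"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        tables[f"{target}-{other}"] = table
        union.update(table["variant"].head(top_k))
    return sorted(union), tables
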