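"""Plain-text readers and writers for the pipeline's exchange formats.

All files are TSV with a header. The summary-statistics schema
(``variant, effect_allele, other_allele, eaf, beta, se, p, n``) matches the
layout of deposited GWAS summary-association files; the transposed genotype
format (one row per variant: id, alleles, then one dosage per individual)
follows PLINK's ``.traw`` spirit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    AlleleFrequencyTable,
    AncestryProportions,
    GenotypeMatrix,
    SchemaError,
    SUMMARY_STAT_COLUMNS,
    validate_summary_stats,
)


def load_summary_stats(path) -> pd.DataFrame:
    """Read a summary-statistics TSV, validating the fixed schema.

    Scientific-notation p-values are parsed exactly by pandas' float reader.
    Raises :class:`SchemaError` naming the offending column on a header
    mismatch.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant": str})
    return validate_summary_stats(df)


def write_summary_stats(df: pd.DataFrame, path) -> None:
    cols = SUMMARY_STAT_COLUMNS + [c for c in df.columns if c not in SUMMARY_STAT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, columns=[c for c in cols if c in df.columns])


def load_panel(path) -> AlleleFrequencyTable:
    """Read a reference allele-frequency table (one frequency column per population)."""
    return AlleleFrequencyTable.from_frame(pd.read_csv(path, sep="\t"))


def write_panel(panel: AlleleFrequencyTable, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_exclusion_list(path) -> pd.DataFrame:
    """Read the static exclusion list (``variant, trait, p``) standing in for a PheWAS."""
    df = pd.read_csv(path, sep="\t", dtype={"variant": str, "trait": str})
    missing = {"variant", "trait", "p"} - set(df.columns)
    if missing:
        raise SchemaError(f"exclusion list missing column(s): {sorted(missing)}")
    return df


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Write a transposed genotype TSV: one row per variant, one column per individual."""
    with open(path, "w") as fh:
        fh.write("variant\teffect_allele\tother_allele\t")
        fh.write("\t".join(str(i) for i in genotypes.individual_ids))
        fh.write("\n")
        for j in range(genotypes.n_variants):
            row = genotypes.dosage[:, j]
            fh.write(
                f"{genotypes.variant_ids[j]}\t{genotypes.effect_alleles[j]}\t"
                f"{genotypes.other_alleles[j]}\t"
            )
            fh.write("\t".join("NA" if d < 0 else str(int(d)) for d in row))
            fh.write("\n")


def load_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    fixed = ["variant", "effect_allele", "other_allele"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise SchemaError(f"genotype file missing column(s): {sorted(missing)}")
    iids = [c for c in df.columns if c not in fixed]
    dosage = df[iids].to_numpy(dtype=float)
    dosage = np.where(np.isnan(dosage), -1, dosage).astype(np.int8).T
    return GenotypeMatrix(
        individual_ids=np.array(iids, dtype=object),
        variant_ids=df["variant"].to_numpy(dtype=object),
        dosage=dosage,
        effect_alleles=df["effect_allele"].to_numpy(dtype=object),
        other_alleles=df["other_allele"].to_numpy(dtype=object),
    )


def write_phenotypes(cohort, path) -> None:
    """Write the phenotype TSV (`iid, outcome_binary, outcome_continuous, age, sex`)."""
    pd.DataFrame(
        {
            "iid": cohort.genotypes.individual_ids,
            "outcome_binary": cohort.outcome_binary,
            "outcome_continuous": cohort.outcome_continuous,
            "age": cohort.age,
            "sex": cohort.sex,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"iid", "outcome_binary", "outcome_continuous", "age", "sex"} - set(
        df.columns
    )
    if missing:
        raise SchemaError(f"phenotype file missing column(s): {sorted(missing)}")
    return df


def write_q_matrix(ancestry: AncestryProportions, path) -> None:
    """Write the ancestry Q matrix TSV (`iid, pop1..popK[, loglik, converged]`)."""
    ancestry.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_q_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
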