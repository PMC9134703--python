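"""Readers and writers for the pipeline's interchange formats.

* genotype dosages: TSV with rows = variants, columns = individuals
  (first columns ``snp_id`` and optionally ``effect_allele``), or a VCF whose
  GT fields are summed into dosages (``./.`` becomes missing);
* phenotypes: long-format CSV (participant_id, visit_age, variable, value),
  with a wide-format converter;
* summary statistics: TSV with header (snp_id, effect_allele, or, p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_summary_stats",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "read_vcf_dosages",
    "write_long_phenotypes",
    "read_long_phenotypes",
    "wide_to_long",
    "long_to_wide",
]


def read_summary_stats(path) -> pd.DataFrame:
    """GWAS summary statistics TSV: snp_id, effect_allele, or (or beta), p."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "effect_allele": str})
    required = {"snp_id", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"summary stats must contain columns {sorted(required)}")
    if "beta" not in df.columns and "or" in df.columns:
        df["beta"] = np.log(pd.to_numeric(df["or"]))
    return df


def write_dosage_tsv(dosages: pd.DataFrame, path, effect_alleles: pd.Series | None = None) -> None:
    """Write dosages (individuals x variants) as a variants-by-individuals TSV."""
    out = dosages.T
    out.index.name = "snp_id"
    out = out.reset_index()
    if effect_alleles is not None:
        out.insert(1, "effect_allele", effect_alleles.reindex(out["snp_id"]).to_numpy())
    out.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a variants-by-individuals dosage TSV; returns (individuals x variants,
    effect alleles or None)."""
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns:
        raise ValueError("dosage TSV must have a snp_id column")
    df = df.set_index("snp_id")
    alleles = None
    if "effect_allele" in df.columns:
        alleles = df.pop("effect_allele")
    dosages = df.T.astype(float)
    dosages.index.name = "participant_id"
    return dosages, alleles


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.Series]:
    """Dosages from a VCF's GT fields (ALT-allele count; ``./.`` -> missing).

    Returns (individuals x variants dosage frame, counted-allele Series).
    The counted allele is ALT, matching the returned dosage convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    ids, alts, rows = [], [], []
    for rec in vcf:
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        alts.append(rec.ALT[0] if rec.ALT else ".")
        gts = rec.genotype.array()[:, :2]
        dos = gts.sum(axis=1).astype(float)
        dos[(gts < 0).any(axis=1)] = np.nan
        rows.append(dos)
    dosages = pd.DataFrame(
        np.asarray(rows).T, index=pd.Index(samples, name="participant_id"), columns=ids
    )
    return dosages, pd.Series(alts, index=ids, name="effect_allele")


def write_long_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_long_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    key_cols = [c for c in ("participant_id", "visit_age", "age", "variable", "region", "test") if c in df.columns]
    if "participant_id" not in key_cols:
        raise ValueError("long phenotype CSV must have a participant_id column")
    age_col = "visit_age" if "visit_age" in df.columns else "age"
    if age_col in df.columns:
        group_keys = [c for c in key_cols if c != age_col]
        bad = []
        for pid, g in df.groupby("participant_id"):
            sub_keys = [c for c in ("variable", "region", "test") if c in g.columns]
            grouped = g.groupby(sub_keys) if sub_keys else [(None, g)]
            for _, gg in grouped:
                ages = gg[age_col].to_numpy(dtype=float)
                if len(ages) > 1 and not np.all(np.diff(ages) > 0):
                    bad.append(pid)
                    break
        if bad:
            raise ValueError(f"non-increasing visit ages for participant(s): {sorted(set(bad))}")
    return df


def wide_to_long(df: pd.DataFrame, id_cols=("participant_id", "visit_age")) -> pd.DataFrame:
    """Wide visit table -> long (participant_id, visit_age, variable, value)."""
    return df.melt(id_vars=list(id_cols), var_name="variable", value_name="value")


def long_to_wide(df: pd.DataFrame, id_cols=("participant_id", "visit_age")) -> pd.DataFrame:
    dup = df.duplicated(subset=[*id_cols, "variable"])
    if dup.any():
        raise ValueError("duplicate participant-visit-variable keys")
    return df.pivot_table(
        index=list(id_cols), columns="variable", values="value", aggfunc="first"
    ).reset_index()
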