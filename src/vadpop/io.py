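"""Readers and writers for the package's delimited schemas, plus VCF ingestion.

All delimited files are tab-separated UTF-8 with a mandatory header and
decimal points.  Frequency tables use columns
``snp_id  chrom  pos  allele_ref  allele_eff  freq_<GROUP> ...`` with one
row per SNP; positions are 1-based as in VCF.  Cohort tables use
``subject_id  ethnicity  age_years  pregnant  pir  retinol_umol_L``
plus optional ``genotype_rs10882272``, ``genotype_rs738409`` and
``weight`` columns.

The optional VCF path maps user-declared per-population allele-frequency
INFO keys to group names (source databases name these fields
inconsistently); frequencies are taken for the alternate allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype_risk import LOCUS_A, LOCUS_B, normalize_genotype

__all__ = [
    "COHORT_COLUMNS",
    "RunConfig",
    "read_frequency_table",
    "write_frequency_table",
    "read_frequency_vcf",
    "read_cohort",
    "write_cohort",
    "load_config",
]

logger = logging.getLogger(__name__)

#: mandatory cohort columns; genotypes and weight are optional
COHORT_COLUMNS = (
    "subject_id",
    "ethnicity",
    "age_years",
    "pregnant",
    "pir",
    "retinol_umol_L",
)
_FREQ_FIXED = ("snp_id", "chrom", "pos", "allele_ref", "allele_eff")


def _validate_frequency_table(df: pd.DataFrame, path) -> pd.DataFrame:
    missing = [c for c in _FREQ_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    if not freq_cols:
        raise ValueError(f"{path}: no freq_<GROUP> columns found")
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"{path}: duplicate snp_id values {dups}")
    for col in freq_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals > 1)]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: column {col} has frequencies outside [0, 1] or "
                f"unparseable at line(s) {[int(i) + 2 for i in bad]}"
            )
        df[col] = vals
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if ((pos.notna()) & (pos < 1)).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    return df


def read_frequency_table(path) -> pd.DataFrame:
    """Read and validate a delimited population frequency table."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        logger.warning("%s: frequency table is empty (header only)", path)
    return _validate_frequency_table(df, path)


def write_frequency_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_frequency_vcf(path, af_keys: dict[str, str]) -> pd.DataFrame:
    """Ingest per-population alternate-allele frequencies from a VCF.

    ``af_keys`` maps group name -> INFO key (e.g. ``{"AFR": "AF_afr"}``).
    Multi-allelic records are rejected; frequencies attach to the alternate
    allele, positions stay 1-based as in the source.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        available = set(vcf.header.info.keys())
        unknown = [k for k in af_keys.values() if k not in available]
        if unknown:
            raise KeyError(
                f"{path}: INFO key(s) {unknown} not declared in header; "
                f"available: {sorted(available)}"
            )
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: record {rec.id or rec.pos} is not biallelic"
                )
            row = {
                "snp_id": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom,
                "pos": rec.pos,
                "allele_ref": rec.ref,
                "allele_eff": rec.alts[0],
            }
            for group, key in af_keys.items():
                val = rec.info.get(key)
                if isinstance(val, tuple):
                    val = val[0]
                if val is None:
                    raise ValueError(
                        f"{path}: record {row['snp_id']} lacks INFO/{key}"
                    )
                row[f"freq_{group}"] = float(val)
            rows.append(row)
    df = pd.DataFrame(rows, columns=[*_FREQ_FIXED, *(f"freq_{g}" for g in af_keys)])
    return _validate_frequency_table(df, path)


def read_cohort(path) -> pd.DataFrame:
    """Read and type a cohort table.

    Mandatory columns are checked by name; unparseable numeric cells become
    missing with a logged count (they surface later in exclusion logs);
    genotype spellings are normalised (e.g. "CT" -> "TC").
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory cohort column(s) {missing}")
    for col in ("age_years", "pregnant", "pir", "retinol_umol_L", "weight"):
        if col in df.columns:
            raw = df[col]
            df[col] = pd.to_numeric(raw, errors="coerce")
            n_bad = int((df[col].isna() & raw.notna()).sum())
            if n_bad:
                logger.warning("%s: %d unparseable %s cells set to missing", path, n_bad, col)
    for col, locus in (
        ("genotype_rs10882272", LOCUS_A),
        ("genotype_rs738409", LOCUS_B),
    ):
        if col in df.columns:
            present = df[col].notna()
            df.loc[present, col] = df.loc[present, col].map(
                lambda g: normalize_genotype(g, locus)
            )
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Declarative run configuration (YAML, nested sections).

    Sections: ``inputs`` (paths + schema names), ``thresholds`` (see
    prevalence module), ``differentiation`` (B, conventions,
    exclude_panel_from_background), ``frequency_model`` and
    ``cohort_model`` (generator parameters), ``output_dir``.  The seed is
    mandatory, either here or as a CLI flag, and is echoed into every
    output.
    """

    seed: int | None = None
    inputs: dict = dc_field(default_factory=dict)
    thresholds: dict = dc_field(default_factory=dict)
    differentiation: dict = dc_field(default_factory=dict)
    frequency_model: dict = dc_field(default_factory=dict)
    cohort_model: dict = dc_field(default_factory=dict)
    output_dir: str = "."


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, ignoring unknown top-level keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        logger.warning("%s: ignoring unknown config keys %s", path, sorted(unknown))
    return RunConfig(**{k: v for k, v in raw.items() if k in known})
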