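"""Two-locus risk-genotype classification and Hardy--Weinberg expectations.

The two loci are the retinol-associated variants rs10882272 (T/C, risk
allele C, near RBP4/FFAR4) and rs738409 (C/G, risk allele G, the PNPLA3
I148M missense change).  An individual is classified "higher risk" when
homozygous for the risk allele at one or both loci; the fully protective
combination (rs10882272 T/T with rs738409 C/C) is flagged separately.
Observed combination proportions per group can be compared with the
proportions expected under Hardy--Weinberg equilibrium and inter-locus
independence, computed from allele frequencies alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "RiskCategory",
    "RiskClassification",
    "ComboTable",
    "normalize_genotype",
    "classify_two_locus",
    "combo_proportions",
    "hwe_expected_combinations",
    "group_risk_report",
    "LOCUS_A",
    "LOCUS_B",
]

logger = logging.getLogger(__name__)

#: (non-risk allele, risk allele) per locus
LOCUS_A = ("T", "C")  # rs10882272
LOCUS_B = ("C", "G")  # rs738409

_GENOTYPE_ORDER_A = ("TT", "TC", "CC")
_GENOTYPE_ORDER_B = ("CC", "CG", "GG")


class RiskCategory(str, Enum):
    """Mutually exclusive and exhaustive two-locus risk categories.

    The fully protective genotype pair is a sub-label of
    ``no_risk_homozygote`` (see :class:`RiskClassification`), not a fifth
    partition cell.
    """

    double_risk_homozygote = "double_risk_homozygote"
    single_risk_homozygote_A = "single_risk_homozygote_A"
    single_risk_homozygote_B = "single_risk_homozygote_B"
    no_risk_homozygote = "no_risk_homozygote"


@dataclass(frozen=True)
class RiskClassification:
    category: RiskCategory
    higher_risk: bool
    double_protective: bool


def normalize_genotype(genotype: str, locus: tuple[str, str]) -> str:
    """Canonical spelling of an unordered, phase-free genotype.

    Accepts "TC", "CT", "T/C" etc.; returns the two alleles with the
    non-risk allele first (e.g. "TC" for a rs10882272 heterozygote).
    """
    if not isinstance(genotype, str):
        raise ValueError(f"genotype must be a string, got {genotype!r}")
    alleles = [a for a in genotype.upper().replace("/", "").replace("|", "")]
    if len(alleles) != 2 or any(a not in locus for a in alleles):
        raise ValueError(
            f"invalid genotype {genotype!r} for locus with alleles {locus}"
        )
    nonrisk, risk = locus
    n_risk = alleles.count(risk)
    return nonrisk * (2 - n_risk) + risk * n_risk


def _risk_copies(genotype: str, locus: tuple[str, str]) -> int:
    return normalize_genotype(genotype, locus).count(locus[1])


def classify_two_locus(genotype_a: str, genotype_b: str) -> RiskClassification:
    """Classify one individual's genotype pair.

    double_risk iff (C/C, G/G); higher_risk iff risk-homozygous at either
    locus; double_protective iff (T/T, C/C).
    """
    a_hom = _risk_copies(genotype_a, LOCUS_A) == 2
    b_hom = _risk_copies(genotype_b, LOCUS_B) == 2
    if a_hom and b_hom:
        cat = RiskCategory.double_risk_homozygote
    elif a_hom:
        cat = RiskCategory.single_risk_homozygote_A
    elif b_hom:
        cat = RiskCategory.single_risk_homozygote_B
    else:
        cat = RiskCategory.no_risk_homozygote
    return RiskClassification(
        category=cat,
        higher_risk=a_hom or b_hom,
        double_protective=(
            _risk_copies(genotype_a, LOCUS_A) == 0
            and _risk_copies(genotype_b, LOCUS_B) == 0
        ),
    )


@dataclass
class ComboTable:
    """Per-group 3x3 genotype-combination tables and risk summaries."""

    counts: dict[str, pd.DataFrame]
    proportions: dict[str, pd.DataFrame]
    summary: pd.DataFrame  # per group: n, higher_risk, double_risk, double_protective


def combo_proportions(
    genotypes: pd.DataFrame,
    group_col: str = "group",
    locus_a_col: str = "genotype_rs10882272",
    locus_b_col: str = "genotype_rs738409",
) -> ComboTable:
    """Tabulate the 9 two-locus genotype combinations per group.

    Rows of each 3x3 table are rs10882272 genotypes (TT, TC, CC), columns
    rs738409 (CC, CG, GG).  Empty groups are omitted with a log entry.
    """
    counts: dict[str, pd.DataFrame] = {}
    props: dict[str, pd.DataFrame] = {}
    rows = []
    for group, grp in genotypes.groupby(group_col, observed=True):
        if grp.empty:
            logger.warning("empty group %s omitted", group)
            continue
        ga = grp[locus_a_col].map(lambda g: normalize_genotype(g, LOCUS_A))
        gb = grp[locus_b_col].map(lambda g: normalize_genotype(g, LOCUS_B))
        ct = (
            pd.crosstab(ga, gb)
            .reindex(index=_GENOTYPE_ORDER_A, columns=_GENOTYPE_ORDER_B, fill_value=0)
            .astype(int)
        )
        ct.index.name = "rs10882272"
        ct.columns.name = "rs738409"
        n = int(ct.to_numpy().sum())
        counts[group] = ct
        props[group] = ct / n
        a_hom = ga == "CC"
        b_hom = gb == "GG"
        rows.append(
            {
                "group": group,
                "n": n,
                "higher_risk": float((a_hom | b_hom).mean()),
                "double_risk": float((a_hom & b_hom).mean()),
                "double_protective": float(((ga == "TT") & (gb == "CC")).mean()),
            }
        )
    summary = pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame()
    return ComboTable(counts=counts, proportions=props, summary=summary)


def _hwe_vector(f: float) -> np.ndarray:
    """HWE genotype proportions ordered by risk-allele copies (0, 1, 2)."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"allele frequency must lie in [0, 1], got {f}")
    return np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])


def hwe_expected_combinations(freq_a: float, freq_b: float):
    """Expected 3x3 combination proportions under HWE and independence.

    Returns ``(table, higher_risk)`` where ``table`` is the outer product of
    the per-locus HWE vectors (sums to 1 exactly) and ``higher_risk`` is the
    probability of being risk-homozygous at one or both loci,
    ``fA^2 + fB^2 - fA^2 fB^2``.
    """
    pa, pb = _hwe_vector(freq_a), _hwe_vector(freq_b)
    table = pd.DataFrame(
        np.outer(pa, pb), index=list(_GENOTYPE_ORDER_A), columns=list(_GENOTYPE_ORDER_B)
    )
    table.index.name = "rs10882272"
    table.columns.name = "rs738409"
    higher = freq_a**2 + freq_b**2 - freq_a**2 * freq_b**2
    return table, float(higher)


def group_risk_report(
    data: pd.DataFrame,
    group_col: str = "group",
    freq_a_col: str | None = None,
    freq_b_col: str | None = None,
) -> pd.DataFrame:
    """Per-group higher-risk proportions, observed or HWE-expected.

    When ``data`` carries genotype columns, the observed carrier proportion
    is reported (source "observed").  When it carries per-group allele
    frequencies for the two loci (``freq_a_col`` / ``freq_b_col``, or
    columns named ``freq_rs10882272`` / ``freq_rs738409``), the
    HWE-expected proportion is reported (source "hwe_expected").
    """
    if {"genotype_rs10882272", "genotype_rs738409"} <= set(data.columns):
        combo = combo_proportions(data, group_col=group_col)
        out = combo.summary[["n", "higher_risk", "double_risk"]].reset_index()
        out["source"] = "observed"
        return out

    fa_col = freq_a_col or "freq_rs10882272"
    fb_col = freq_b_col or "freq_rs738409"
    missing = [c for c in (fa_col, fb_col) if c not in data.columns]
    if missing:
        raise KeyError(
            f"need genotype columns or frequency columns; missing {missing}"
        )
    rows = []
    for _, row in data.iterrows():
        _, higher = hwe_expected_combinations(float(row[fa_col]), float(row[fb_col]))
        double = float(row[fa_col]) ** 2 * float(row[fb_col]) ** 2
        rows.append(
            {
                "group": row[group_col],
                "n": pd.NA,
                "higher_risk": higher,
                "double_risk": double,
                "source": "hwe_expected",
            }
        )
    return pd.DataFrame(rows)
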