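"""Packaged in-study count tables and published allele-frequency vectors.

The package ships, as small tab-delimited files, the printed summary data of
the source analyses: the Bronx third-trimester VAD/VAS counts by ethnicity,
the NHANES (2001--2006 cycles) deficient/sufficient counts per ethnicity
stratum, the ALFA and PAGE per-population frequencies of the rs10882272 C
allele, the PAGE frequencies of the rs738409 G allele, and the TOPMed
observed higher-risk-carrier percentages.  These let the prevalence,
exact-test and risk-classification stages run on real published numbers
without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "fixture_tables",
    "fixture_names",
    "load_fixture",
    "bronx_counts",
    "nhanes_counts",
    "alfa_rs10882272",
    "page_rs10882272",
    "page_rs738409",
    "topmed_risk_observed",
    "TOPMED_FREQ",
]

_FILES = {
    "bronx_table1_counts": "bronx_table1_counts.tsv",
    "nhanes_table2_counts": "nhanes_table2_counts.tsv",
    "alfa_rs10882272": "alfa_rs10882272.tsv",
    "page_rs10882272": "page_rs10882272.tsv",
    "page_rs738409": "page_rs738409.tsv",
    "topmed_risk_observed": "topmed_risk_observed.tsv",
}

#: TOPMed per-group risk-allele frequencies quoted in the source analysis
#: (rs10882272 C in non-Hispanic Blacks; rs738409 G in Mexicans and Asians).
TOPMED_FREQ = {
    ("rs10882272", "Non-Hispanic Black"): 0.61,
    ("rs738409", "Mexican"): 0.45,
    ("rs738409", "Asian"): 0.39,
}


def fixture_names() -> list[str]:
    """Names of the packaged tables, for discovery (also used by the CLI)."""
    return sorted(_FILES)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged table by name (see :func:`fixture_names`)."""
    try:
        fname = _FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    with resources.files("vadpop.data").joinpath(fname).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def bronx_counts() -> pd.DataFrame:
    """Bronx VAD/VAS counts by ethnicity: (29, 15), (8, 7), (3, 5)."""
    return load_fixture("bronx_table1_counts")


def nhanes_counts() -> pd.DataFrame:
    """NHANES deficient/sufficient counts per ethnicity x stratum."""
    return load_fixture("nhanes_table2_counts")


def alfa_rs10882272() -> pd.DataFrame:
    """ALFA rs10882272 C-allele frequency table (4 population groups)."""
    return load_fixture("alfa_rs10882272")


def page_rs10882272() -> pd.DataFrame:
    """PAGE rs10882272 C-allele frequency table (7 Hispanic/Latino and
    Native American groups)."""
    return load_fixture("page_rs10882272")


def page_rs738409() -> pd.DataFrame:
    """PAGE rs738409 G-allele frequency table (6 groups)."""
    return load_fixture("page_rs738409")


def topmed_risk_observed() -> pd.DataFrame:
    """TOPMed observed higher-risk-carrier percentages per group."""
    return load_fixture("topmed_risk_observed")


def fixture_tables() -> dict[str, pd.DataFrame]:
    """All packaged tables as a name -> DataFrame mapping."""
    return {name: load_fixture(name) for name in _FILES}
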