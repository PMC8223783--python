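"""Synthetic allele-frequency backgrounds, SNP panels, genotypes and cohorts.

Every downstream stage of the pipeline (prevalence estimation, the SNP-panel
dispersion test, two-locus risk classification) is exercisable on data drawn
from the generative models here, with no external downloads.

Models
------
* Population allele frequencies follow the Balding--Nichols model: for a SNP
  with ancestral frequency ``p`` and divergence parameter ``F`` (an FST
  scale), each population's frequency is an independent draw from
  ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
  ``F p (1-p)``.
* Genotypes at the two retinol-associated loci (rs10882272 T/C, risk allele
  C; rs738409 C/G, risk allele G) are drawn under Hardy--Weinberg
  equilibrium, independently at the two loci (they lie on different
  chromosomes, so no linkage is modelled).
* Serum retinol is log-normal.  Each copy of the rs10882272 C allele
  multiplies the mean by ``1 - per_allele_decrement`` (default 0.03, i.e. a
  3% decrement per copy); pregnancy applies a further multiplicative shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "FrequencyModelConfig",
    "CohortModelConfig",
    "gen_background_frequencies",
    "gen_panel_frequencies",
    "gen_genotypes",
    "gen_cohort",
    "LOCUS_A_GENOTYPES",
    "LOCUS_B_GENOTYPES",
]

#: canonical genotype spellings, indexed by risk-allele copy number
LOCUS_A_GENOTYPES = ("TT", "TC", "CC")  # rs10882272, risk allele C
LOCUS_B_GENOTYPES = ("CC", "CG", "GG")  # rs738409, risk allele G

_ANCESTRY_LABELS = ("AFR", "AMR", "EAS", "EUR", "SAS")


class ConfigurationError(ValueError):
    """Raised when a generator or analysis configuration is invalid."""


def _group_labels(k: int) -> tuple[str, ...]:
    if k <= len(_ANCESTRY_LABELS):
        return _ANCESTRY_LABELS[:k]
    return tuple(f"GRP{i + 1}" for i in range(k))


@dataclass
class FrequencyModelConfig:
    """Parameters of the Balding--Nichols frequency simulation.

    Parameters
    ----------
    n_groups
        Number of population groups K (>= 2).  Defaults to 5, emulating the
        five continental ancestry groups of large reference panels.
    fst_background, fst_panel
        Divergence parameters in (0, 1) for the genome-wide background and
        for the trait-associated panel.  A panel with ``fst_panel >
        fst_background`` emulates a SNP set under divergent selection or
        ancestry-correlated trait architecture.
    n_background
        Number of background SNPs.
    panel_size
        Number of panel SNPs (default 39, the size of the published
        vitamin A-related SNP set).
    ancestral_freq_range
        Support of the uniform law for the ancestral frequency ``p``
        (default [0.05, 0.95], avoiding degenerate fixed SNPs).
    seed
        Mandatory RNG seed; all outputs are bit-reproducible under it.
    """

    n_groups: int = 5
    fst_background: float = 0.05
    fst_panel: float = 0.3
    n_background: int = 2000
    panel_size: int = 39
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    group_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ConfigurationError(f"n_groups must be >= 2, got {self.n_groups}")
        for name in ("fst_background", "fst_panel"):
            f = getattr(self, name)
            if not (0.0 < f < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {f}")
        if self.panel_size < 1:
            raise ConfigurationError(f"panel_size must be >= 1, got {self.panel_size}")
        if self.n_background < self.panel_size:
            raise ConfigurationError(
                f"n_background ({self.n_background}) must be >= panel_size "
                f"({self.panel_size})"
            )
        lo, hi = self.ancestral_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                f"ancestral_freq_range must satisfy 0 <= lo <= hi <= 1, got {lo, hi}"
            )
        if self.group_labels is not None and len(self.group_labels) != self.n_groups:
            raise ConfigurationError("group_labels length must equal n_groups")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.group_labels or _group_labels(self.n_groups)


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, fst: float, k: int
) -> np.ndarray:
    """Draw per-group frequencies for SNPs with ancestral frequencies ``p``."""
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a[:, None], b[:, None], size=(p.size, k))


def _freq_frame(
    snp_ids: list[str], freqs: np.ndarray, labels: tuple[str, ...], chrom: str = "sim"
) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": np.arange(1, len(snp_ids) + 1),
            "allele_ref": "A",
            "allele_eff": "B",
        }
    )
    for j, g in enumerate(labels):
        out[f"freq_{g}"] = freqs[:, j]
    return out


def gen_background_frequencies(config: FrequencyModelConfig) -> pd.DataFrame:
    """Simulate a genome-wide background of per-population allele frequencies.

    Returns a frequency table of ``n_background`` SNPs by ``n_groups``
    populations under the Balding--Nichols model at ``fst_background``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, config.n_background)
    freqs = _balding_nichols(rng, p, config.fst_background, config.n_groups)
    ids = [f"bg_{i:07d}" for i in range(config.n_background)]
    return _freq_frame(ids, freqs, config.labels)


def gen_panel_frequencies(config: FrequencyModelConfig) -> pd.DataFrame:
    """Simulate the trait-associated SNP panel at ``fst_panel``.

    SNP ids are disjoint from the background's, so the two tables can be
    combined or kept separate downstream.  A separate RNG stream (offset
    seed) keeps the panel independent of the background drawn from the same
    config.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, config.panel_size)
    freqs = _balding_nichols(rng, p, config.fst_panel, config.n_groups)
    ids = [f"panel_{i:04d}" for i in range(config.panel_size)]
    return _freq_frame(ids, freqs, config.labels)


def _draw_genotypes(
    rng: np.random.Generator, freq: float, n: int, spellings: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    if not (0.0 <= freq <= 1.0):
        raise ConfigurationError(f"allele frequency must lie in [0, 1], got {freq}")
    copies = rng.binomial(2, freq, size=n)
    return copies, np.asarray(spellings)[copies]


def gen_genotypes(
    freq_a,
    freq_b,
    n_per_group,
    group_labels=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw two-locus HWE genotypes for one or more population groups.

    Parameters
    ----------
    freq_a, freq_b
        Risk-allele frequency at rs10882272 (C) and rs738409 (G), one value
        per group (scalars are treated as a single group).
    n_per_group
        Individuals per group.
    group_labels
        Group names; defaults to ``group1 .. groupK``.

    The two loci are drawn independently (different chromosomes); within a
    locus, genotype counts follow Hardy--Weinberg proportions
    ``((1-f)^2, 2f(1-f), f^2)``.
    """
    fa = np.atleast_1d(np.asarray(freq_a, dtype=float))
    fb = np.atleast_1d(np.asarray(freq_b, dtype=float))
    ns = np.atleast_1d(np.asarray(n_per_group, dtype=int))
    if not (fa.shape == fb.shape == ns.shape):
        raise ConfigurationError("freq_a, freq_b and n_per_group must have equal length")
    if group_labels is None:
        group_labels = [f"group{i + 1}" for i in range(len(ns))]
    if len(group_labels) != len(ns):
        raise ConfigurationError("group_labels length must match n_per_group")

    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for g, f_a, f_b, n in zip(group_labels, fa, fb, ns):
        _, geno_a = _draw_genotypes(rng, f_a, n, LOCUS_A_GENOTYPES)
        _, geno_b = _draw_genotypes(rng, f_b, n, LOCUS_B_GENOTYPES)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"S{offset + i:06d}" for i in range(n)],
                    "group": g,
                    "genotype_rs10882272": geno_a,
                    "genotype_rs738409": geno_b,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


@dataclass
class CohortModelConfig:
    """Parameters of the synthetic serum-retinol cohort.

    Defaults are seeded by published per-group allele frequencies of the two
    risk loci (rs10882272 C: 0.617 African American / 0.260 Mexican / 0.106
    Asian; rs738409 G: 0.144 / 0.50 / 0.44) and give total VAD prevalences
    in the low-percent to low-teens range typical of survey data.

    Retinol for individual i is

    ``exp(baseline[g(i)] + n_C(i) * log(1 - per_allele_decrement)
          + pregnant(i) * log(pregnancy_effect) + eps_i)``,

    ``eps_i ~ Normal(0, sigma_log)``, so the mean ratio between risk-allele
    homozygotes and non-carriers is exactly ``(1 - per_allele_decrement)^2``.
    """

    group_labels: tuple[str, ...] = (
        "Non-Hispanic Black",
        "Mexican American",
        "Asian",
    )
    n_per_group: tuple[int, ...] = (976, 1071, 500)
    risk_freq_a: tuple[float, ...] = (0.617, 0.260, 0.106)
    risk_freq_b: tuple[float, ...] = (0.144, 0.50, 0.44)
    baseline_log_retinol: tuple[float, ...] = (0.33, 0.42, 0.46)
    per_allele_decrement: float = 0.03
    pregnancy_effect: float = 0.8
    pregnancy_rate: float = 0.25
    pir_shape: float = 2.0
    pir_scale: float = 1.0
    age_range: tuple[int, int] = (17, 42)
    sigma_log: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.group_labels)
        for name in ("n_per_group", "risk_freq_a", "risk_freq_b", "baseline_log_retinol"):
            if len(getattr(self, name)) != k:
                raise ConfigurationError(f"{name} must have one entry per group")
        for f in (*self.risk_freq_a, *self.risk_freq_b):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"allele frequency outside [0, 1]: {f}")
        if not (0.0 <= self.per_allele_decrement < 1.0):
            raise ConfigurationError("per_allele_decrement must lie in [0, 1)")
        if self.pregnancy_effect <= 0:
            raise ConfigurationError("pregnancy_effect must be positive")
        if not (0.0 <= self.pregnancy_rate <= 1.0):
            raise ConfigurationError("pregnancy_rate must lie in [0, 1]")
        if self.sigma_log < 0:
            raise ConfigurationError("sigma_log must be non-negative")


def gen_cohort(config: CohortModelConfig) -> pd.DataFrame:
    """Simulate an individual-level cohort table.

    One record per individual with ethnicity, age (years, uniform over
    ``age_range``), pregnancy flag, poverty-income ratio (Gamma), serum
    retinol (µmol/L, log-normal with genotype and pregnancy effects) and the
    two-locus genotypes that generated the retinol values.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    offset = 0
    for g_idx, label in enumerate(config.group_labels):
        n = config.n_per_group[g_idx]
        copies_a, geno_a = _draw_genotypes(
            rng, config.risk_freq_a[g_idx], n, LOCUS_A_GENOTYPES
        )
        _, geno_b = _draw_genotypes(rng, config.risk_freq_b[g_idx], n, LOCUS_B_GENOTYPES)
        pregnant = rng.random(n) < config.pregnancy_rate
        log_ret = (
            config.baseline_log_retinol[g_idx]
            + copies_a * np.log1p(-config.per_allele_decrement)
            + pregnant * np.log(config.pregnancy_effect)
            + rng.normal(0.0, config.sigma_log, n)
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"S{offset + i:06d}" for i in range(n)],
                    "ethnicity": label,
                    "age_years": rng.integers(
                        config.age_range[0], config.age_range[1] + 1, n
                    ),
                    "pregnant": pregnant.astype(int),
                    "pir": rng.gamma(config.pir_shape, config.pir_scale, n),
                    "retinol_umol_L": np.exp(log_ret),
                    "genotype_rs10882272": geno_a,
                    "genotype_rs738409": geno_b,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)
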