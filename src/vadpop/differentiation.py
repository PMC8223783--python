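"""Cross-population allele-frequency dispersion and the SNP-set permutation test.

The statistic is deliberately plain: for each SNP, the standard deviation of
its allele frequency across the K population groups ("dispersion"); for a
panel of SNPs, the unweighted mean of the per-SNP dispersions.  Whether an
m-SNP panel is more differentiated than expected is judged against a null
built by drawing random m-SNP sets from a genome-wide background and
recording their panel means; the empirical p-value is the fraction of null
draws at least as large as the observed statistic.

Both the SD divisor (sample, K-1, by default) and the p-value convention
(plain r/B by default; add-one (r+1)/(B+1) reported alongside) are recorded
in every result, and the statistic is invariant to which allele is
tabulated (sd(f) = sd(1-f)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DifferentiationResult",
    "freq_columns",
    "freq_matrix",
    "per_snp_dispersion",
    "panel_statistic",
    "permutation_null",
    "matched_permutation_null",
    "empirical_p",
    "run_differentiation",
]

logger = logging.getLogger(__name__)


def freq_columns(table: pd.DataFrame) -> list[str]:
    """The per-group frequency columns (``freq_<GROUP>``) of a table."""
    cols = [c for c in table.columns if c.startswith("freq_")]
    if not cols:
        raise ValueError("table has no freq_<GROUP> columns")
    return cols


def freq_matrix(table: pd.DataFrame) -> np.ndarray:
    """SNP-by-group frequency matrix, validated to lie in [0, 1]."""
    m = table[freq_columns(table)].to_numpy(dtype=float)
    if np.isnan(m).any():
        raise ValueError("frequency table contains missing frequencies")
    if (m < 0).any() or (m > 1).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return m


def per_snp_dispersion(freqs, convention: str = "sample") -> np.ndarray | float:
    """Standard deviation of allele frequency across population groups.

    ``freqs`` is one frequency vector (length K) or an n-by-K matrix.
    ``convention`` selects the divisor: "sample" (K-1, default) or
    "population" (K).  Scalar in, scalar out.
    """
    if convention not in ("sample", "population"):
        raise ValueError(f"unknown SD convention {convention!r}")
    f = np.asarray(freqs, dtype=float)
    scalar = f.ndim == 1
    f = np.atleast_2d(f)
    if f.shape[1] < 2:
        raise ValueError(f"need frequencies for at least 2 groups, got {f.shape[1]}")
    if (f < 0).any() or (f > 1).any() or np.isnan(f).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    s = f.std(axis=1, ddof=1 if convention == "sample" else 0)
    return float(s[0]) if scalar else s


def panel_statistic(
    table: pd.DataFrame, panel, convention: str = "sample"
) -> float:
    """Unweighted mean per-SNP dispersion over the panel members."""
    panel = list(panel)
    if len(panel) != len(set(panel)):
        raise ValueError("panel SNP ids must be unique")
    idx = table.set_index("snp_id")
    missing = [s for s in panel if s not in idx.index]
    if missing:
        raise KeyError(f"panel ids missing from frequency table: {missing}")
    sub = idx.loc[panel].reset_index()
    return float(per_snp_dispersion(freq_matrix(sub), convention).mean())


def permutation_null(
    table: pd.DataFrame,
    m: int,
    B: int = 1000,
    seed: int = 0,
    convention: str = "sample",
) -> np.ndarray:
    """Null distribution of the panel statistic under random SNP sets.

    Each of the B iterations draws m distinct SNPs uniformly without
    replacement from the background table (independently across iterations,
    so a SNP can recur between iterations) and records the mean per-SNP
    dispersion of the draw.
    """
    n = len(table)
    if m < 1 or B < 1:
        raise ValueError("m and B must be >= 1")
    if m > n:
        raise ValueError(f"panel size m={m} exceeds background size {n}")
    disp = per_snp_dispersion(freq_matrix(table), convention)
    rng = np.random.default_rng(seed)
    if B * n <= 50_000_000:
        # vectorised sampling-without-replacement via random-key partition
        keys = rng.random((B, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    else:
        idx = np.stack([rng.choice(n, size=m, replace=False) for _ in range(B)])
    return disp[idx].mean(axis=1)


def _folded_mean_freq(table: pd.DataFrame) -> np.ndarray:
    """Per-SNP mean frequency across groups, folded at 0.5 (a MAF proxy)."""
    mean = freq_matrix(table).mean(axis=1)
    return np.minimum(mean, 1.0 - mean)


def matched_permutation_null(
    background: pd.DataFrame,
    panel_table: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    bins: int = 10,
    convention: str = "sample",
) -> np.ndarray:
    """Frequency-bin-matched null: each draw mirrors the panel's MAF profile.

    SNPs are binned on their cross-group mean frequency folded at 0.5 into
    ``bins`` equal-width bins on [0, 0.5]; each iteration samples, without
    replacement, as many background SNPs per bin as the panel has there.
    Useful when the panel's frequency spectrum differs from the
    background's, which otherwise confounds the dispersion comparison.
    """
    edges = np.linspace(0.0, 0.5, bins + 1)
    bg_bins = np.clip(np.digitize(_folded_mean_freq(background), edges) - 1, 0, bins - 1)
    panel_bins = np.clip(
        np.digitize(_folded_mean_freq(panel_table), edges) - 1, 0, bins - 1
    )
    disp = per_snp_dispersion(freq_matrix(background), convention)
    rng = np.random.default_rng(seed)
    parts = []
    for b in range(bins):
        need = int((panel_bins == b).sum())
        if need == 0:
            continue
        members = np.flatnonzero(bg_bins == b)
        if members.size < need:
            raise ValueError(
                f"background has {members.size} SNPs in frequency bin {b} "
                f"but the panel needs {need}; use fewer bins"
            )
        keys = rng.random((B, members.size))
        idx = members[np.argpartition(keys, need - 1, axis=1)[:, :need]]
        parts.append(disp[idx])
    return np.concatenate(parts, axis=1).mean(axis=1)


def empirical_p(s_obs: float, null_values, convention: str = "ge") -> float:
    """Empirical p-value of the observed statistic against the null draws.

    Conventions: "ge" (default) counts the fraction of null values >= the
    observed one, so 30/1000 = 0.030 is attainable exactly; "add_one" is the
    (r+1)/(B+1) rule.  Ties count toward the tail in both (conservative).
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null_values must be non-empty")
    r = int((null >= s_obs).sum())
    if convention == "ge":
        return r / null.size
    if convention == "add_one":
        return (r + 1) / (null.size + 1)
    raise ValueError(f"unknown p-value convention {convention!r}")


@dataclass
class DifferentiationResult:
    """Full output of the SNP-panel differentiation test."""

    per_snp_dispersion: dict[str, float]
    panel_statistic: float
    null_values: np.ndarray
    p_value: float
    p_value_add_one: float
    B: int
    background_size: int
    seed: int
    dispersion_convention: str
    p_convention: str
    n_groups: int
    excluded_from_background: int = 0

    def null_frame(self) -> pd.DataFrame:
        """Histogram-ready export: null draws plus the observed statistic."""
        df = pd.DataFrame({"statistic": self.null_values})
        df["kind"] = "null"
        obs = pd.DataFrame({"statistic": [self.panel_statistic], "kind": ["observed"]})
        return pd.concat([df, obs], ignore_index=True)

    def plot_null(self, path) -> None:
        """Write a histogram of the null draws with the observed statistic
        marked as a vertical line."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(self.null_values, bins=40, color="0.7", edgecolor="0.4")
        ax.axvline(self.panel_statistic, color="crimson", lw=2,
                   label=f"observed = {self.panel_statistic:.3f}")
        ax.set_xlabel("mean cross-population allele-frequency SD")
        ax.set_ylabel("random SNP sets")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def summary(self) -> dict:
        return {
            "panel_statistic": self.panel_statistic,
            "p_value": self.p_value,
            "p_value_add_one": self.p_value_add_one,
            "B": self.B,
            "panel_size": len(self.per_snp_dispersion),
            "background_size": self.background_size,
            "excluded_from_background": self.excluded_from_background,
            "seed": self.seed,
            "dispersion_convention": self.dispersion_convention,
            "p_convention": self.p_convention,
            "n_groups": self.n_groups,
        }


def run_differentiation(
    background: pd.DataFrame,
    panel_table: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    dispersion_convention: str = "sample",
    p_convention: str = "ge",
    exclude_panel_from_background: bool = True,
    maf_match_bins: int | None = None,
) -> DifferentiationResult:
    """End-to-end panel differentiation test.

    Computes the per-SNP dispersions and panel mean for ``panel_table``,
    builds the permutation null from ``background`` (by default excluding
    any SNP id shared with the panel, logged) and reports the empirical
    p-value under both conventions.  The background and panel must tabulate
    the same population groups.
    """
    bg_groups, panel_groups = set(freq_columns(background)), set(freq_columns(panel_table))
    if bg_groups != panel_groups:
        only_bg = sorted(g[5:] for g in bg_groups - panel_groups)
        only_panel = sorted(g[5:] for g in panel_groups - bg_groups)
        raise ValueError(
            f"group mismatch between background and panel: background-only "
            f"{only_bg}, panel-only {only_panel}"
        )

    bg = background
    n_excluded = 0
    shared = set(bg["snp_id"]) & set(panel_table["snp_id"])
    if shared:
        if exclude_panel_from_background:
            bg = bg[~bg["snp_id"].isin(shared)]
            n_excluded = len(shared)
            logger.info(
                "excluded %d panel SNPs from the permutation background", n_excluded
            )
        else:
            logger.info("%d panel SNPs retained in the background", len(shared))

    disp = per_snp_dispersion(freq_matrix(panel_table), dispersion_convention)
    s_obs = float(np.mean(disp))
    if maf_match_bins is not None:
        null = matched_permutation_null(
            bg, panel_table, B=B, seed=seed, bins=maf_match_bins,
            convention=dispersion_convention,
        )
    else:
        null = permutation_null(
            bg, m=len(panel_table), B=B, seed=seed, convention=dispersion_convention
        )
    return DifferentiationResult(
        per_snp_dispersion=dict(zip(panel_table["snp_id"], np.atleast_1d(disp))),
        panel_statistic=s_obs,
        null_values=null,
        p_value=empirical_p(s_obs, null, p_convention),
        p_value_add_one=empirical_p(s_obs, null, "add_one"),
        B=B,
        background_size=len(bg),
        seed=seed,
        dispersion_convention=dispersion_convention,
        p_convention=p_convention,
        n_groups=len(bg_groups),
        excluded_from_background=n_excluded,
    )
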