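"""Vitamin A status classification, stratified prevalence and exact tests.

Deficiency is defined on serum retinol: a record is vitamin A deficient
(VAD) when retinol is strictly below 1.05 µmol/L, and severely deficient
below 0.70 µmol/L (the WHO supplementation trigger asks whether >= 20% of
pregnant women fall below the severe cutoff).  Prevalence per stratum is an
unweighted count ratio with a Wilson score interval by default; two-group
comparisons use Fisher's exact test with the conditional-MLE odds ratio and
its exact interval, matching R's ``fisher.test`` conventions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Thresholds",
    "PrevalenceEstimate",
    "ComparisonResult",
    "CovariateTestResult",
    "classify_vad",
    "add_vad_status",
    "filter_cohort",
    "prevalence_from_counts",
    "stratified_prevalence",
    "compare_proportions",
    "covariate_table",
    "who_supplementation_flag",
]

logger = logging.getLogger(__name__)

_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta", "normal": "normal"}


@dataclass(frozen=True)
class Thresholds:
    """Analysis cutoffs.

    vad_cutoff / severe_cutoff are serum retinol in µmol/L; pir_cutoff is
    the poverty-income ratio bound ("PIR < 1.85" marks the low-income band,
    boundary records fall in the non-poverty band); who_trigger is the
    proportion of pregnant women below severe_cutoff that triggers a
    supplementation recommendation; ages are inclusive bounds in years.
    """

    vad_cutoff: float = 1.05
    severe_cutoff: float = 0.70
    pir_cutoff: float = 1.85
    who_trigger: float = 0.20
    age_min: float = 17.0
    age_max: float = 42.0

    def __post_init__(self) -> None:
        if not (0 < self.severe_cutoff < self.vad_cutoff):
            raise ValueError("need 0 < severe_cutoff < vad_cutoff")
        if min(self.pir_cutoff, self.who_trigger, self.age_min, self.age_max) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class PrevalenceEstimate:
    stratum: str
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    ci_method: str


@dataclass
class ComparisonResult:
    table: np.ndarray
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    p_value: float
    method: str
    degenerate: bool = False


@dataclass
class CovariateTestResult:
    covariate: str
    kind: str  # "continuous" | "categorical"
    statistic: float
    p_value: float
    summaries: dict = field(default_factory=dict)
    test: str = ""


def classify_vad(retinol: float, thresholds: Thresholds = Thresholds()):
    """Classify one serum retinol value (µmol/L).

    Returns ``(status, severe)`` with ``status`` in {"deficient",
    "sufficient"}; deficiency is strict (`< vad_cutoff`), so 1.05 itself is
    sufficient.  Raises ValueError on non-positive or missing input (cohort
    records with such values are excluded, not classified).
    """
    if retinol is None or (isinstance(retinol, float) and math.isnan(retinol)):
        raise ValueError("missing retinol value cannot be classified")
    if retinol <= 0:
        raise ValueError(f"retinol must be positive, got {retinol}")
    status = "deficient" if retinol < thresholds.vad_cutoff else "sufficient"
    return status, bool(retinol < thresholds.severe_cutoff)


def add_vad_status(
    cohort: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Vectorised classification: appends vad_status / severe columns.

    Records with missing or non-positive retinol get NA status and are
    counted in the log; downstream denominators exclude them.
    """
    out = cohort.copy()
    ret = pd.to_numeric(out["retinol_umol_L"], errors="coerce")
    valid = ret.notna() & (ret > 0)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d records with missing/non-positive retinol excluded", n_bad)
    status = pd.Series(pd.NA, index=out.index, dtype="object")
    status[valid & (ret < thresholds.vad_cutoff)] = "deficient"
    status[valid & (ret >= thresholds.vad_cutoff)] = "sufficient"
    out["vad_status"] = status
    out["severe"] = valid & (ret < thresholds.severe_cutoff)
    return out


def filter_cohort(
    cohort: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    required_fields: tuple[str, ...] = ("retinol_umol_L", "pir", "ethnicity"),
):
    """Apply the cohort inclusion rules.

    Keeps records with age in [age_min, age_max] (inclusive) and all
    ``required_fields`` non-missing.  Returns ``(filtered, exclusion_log)``
    where the log maps reason -> count.  Exclusion reasons are assessed on
    the full table, so one record may appear under several reasons; the
    ``total_excluded`` entry counts unique dropped records.
    """
    missing_cols = [c for c in required_fields if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort lacks required columns: {missing_cols}")
    log: dict[str, int] = {}
    keep = pd.Series(True, index=cohort.index)
    if "age_years" in cohort.columns:
        age = pd.to_numeric(cohort["age_years"], errors="coerce")
        in_range = age.between(thresholds.age_min, thresholds.age_max, inclusive="both")
        n = int((~in_range).sum())
        if n:
            log["age_out_of_range"] = n
        keep &= in_range
    for col in required_fields:
        present = cohort[col].notna()
        n = int((~present).sum())
        if n:
            log[f"missing_{col}"] = n
        keep &= present
    log["total_excluded"] = int((~keep).sum())
    filtered = cohort[keep].copy()
    if filtered.empty:
        logger.warning("all %d records excluded by cohort filters", len(cohort))
    return filtered, log


def prevalence_from_counts(
    numerator: int,
    denominator: int,
    stratum: str = "",
    ci_method: str = "wilson",
    alpha: float = 0.05,
) -> PrevalenceEstimate:
    """Proportion deficient with a binomial confidence interval.

    ci_method is one of wilson (default), clopper-pearson, normal.
    """
    if not (0 <= numerator <= denominator) or denominator <= 0:
        raise ValueError(f"invalid counts {numerator}/{denominator}")
    if ci_method not in _CI_METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}; choose from {sorted(_CI_METHODS)}")
    lo, hi = proportion_confint(
        numerator, denominator, alpha=alpha, method=_CI_METHODS[ci_method]
    )
    return PrevalenceEstimate(
        stratum=stratum,
        numerator=int(numerator),
        denominator=int(denominator),
        proportion=numerator / denominator,
        ci_low=float(np.clip(lo, 0, 1)),
        ci_high=float(np.clip(hi, 0, 1)),
        ci_method=ci_method,
    )


def _pir_band(pir: pd.Series, thresholds: Thresholds) -> pd.Series:
    cut = thresholds.pir_cutoff
    band = pd.Series(pd.NA, index=pir.index, dtype="object")
    v = pd.to_numeric(pir, errors="coerce")
    band[v < cut] = f"PIR<{cut}"
    band[v >= cut] = f"PIR>={cut}"  # boundary records fall in the non-poverty band
    return band


def stratified_prevalence(
    data: pd.DataFrame,
    strata: tuple[str, ...] = ("ethnicity",),
    thresholds: Thresholds = Thresholds(),
    ci_method: str = "wilson",
) -> list[PrevalenceEstimate]:
    """Per-stratum VAD prevalence.

    ``data`` is either a count fixture (columns including ``deficient`` and
    ``sufficient``, one row per stratum — proportions are exact count
    ratios) or an individual-level cohort, in which case records are
    classified on retinol and grouped by the named fields.  Recognised
    stratification fields for cohorts are any cohort columns plus the
    derived ``pir_band`` (split at ``thresholds.pir_cutoff``).  Empty strata
    are omitted with a log entry.
    """
    estimates: list[PrevalenceEstimate] = []
    if {"deficient", "sufficient"} <= set(data.columns):
        label_cols = [c for c in data.columns if c not in ("deficient", "sufficient")]
        for _, row in data.iterrows():
            num, suf = int(row["deficient"]), int(row["sufficient"])
            label = " / ".join(str(row[c]) for c in label_cols) or f"row{_}"
            if num + suf == 0:
                logger.warning("empty stratum %s omitted", label)
                continue
            estimates.append(
                prevalence_from_counts(num, num + suf, label, ci_method=ci_method)
            )
        return estimates

    cohort = add_vad_status(data, thresholds)
    if "pir_band" in strata and "pir_band" not in cohort.columns:
        cohort["pir_band"] = _pir_band(cohort["pir"], thresholds)
    missing = [s for s in strata if s not in cohort.columns]
    if missing:
        raise KeyError(f"unknown stratification fields: {missing}")
    classified = cohort[cohort["vad_status"].notna()]
    for key, grp in classified.groupby(list(strata), dropna=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        label = " / ".join(str(k) for k in key)
        n = len(grp)
        if n == 0:
            logger.warning("empty stratum %s omitted", label)
            continue
        num = int((grp["vad_status"] == "deficient").sum())
        estimates.append(prevalence_from_counts(num, n, label, ci_method=ci_method))
    return estimates


def compare_proportions(table, method: str = "fisher") -> ComparisonResult:
    """Two-group comparison of deficiency proportions on a 2x2 table.

    ``table`` rows are groups, columns are (deficient, sufficient) counts.
    The default method is Fisher's exact test — two-sided by the
    point-probability rule — with the conditional-MLE odds ratio and its
    exact 95% interval (the convention of R's ``fisher.test``).  A
    chi-square two-proportion alternative is available as
    ``method="chi2"`` (odds ratio CI still exact-conditional).

    A zero margin makes the odds ratio undefined: p is reported as 1 and the
    result flagged degenerate.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("zero margin in %s: comparison degenerate", t.tolist())
        return ComparisonResult(
            table=t, odds_ratio=float("nan"), or_ci_low=float("nan"),
            or_ci_high=float("nan"), p_value=1.0, method=method, degenerate=True,
        )
    if method == "fisher":
        p = float(stats.fisher_exact(t).pvalue)
    elif method == "chi2":
        p = float(stats.chi2_contingency(t).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    orr = stats.contingency.odds_ratio(t)  # conditional MLE
    ci = orr.confidence_interval(0.95)
    return ComparisonResult(
        table=t,
        odds_ratio=float(orr.statistic),
        or_ci_low=float(ci.low),
        or_ci_high=float(ci.high),
        p_value=p,
        method=method,
    )


def _exact_2xk_p(counts: np.ndarray) -> float:
    """Exact conditional test for a 2 x k table (R fisher.test convention).

    Enumerates all tables with the observed margins and sums the
    multivariate-hypergeometric probabilities of tables no more probable
    than the observed one.  Intended for the small samples where the exact
    test matters; enumeration is over the k-1 free cells of row one.
    """
    col = counts.sum(axis=0)
    r0 = int(counts.sum(axis=1)[0])
    n_total = int(counts.sum())
    log_denom = math.lgamma(n_total + 1) - math.lgamma(r0 + 1) - math.lgamma(n_total - r0 + 1)

    def log_prob(cells):
        s = -log_denom
        for c, m in zip(cells, col):
            s += math.lgamma(m + 1) - math.lgamma(c + 1) - math.lgamma(m - c + 1)
        return s

    lp_obs = log_prob(counts[0])
    total = 0.0

    def rec(idx, remaining, cells):
        nonlocal total
        if idx == len(col) - 1:
            if remaining <= col[idx]:
                lp = log_prob(cells + [remaining])
                if lp <= lp_obs + 1e-7:
                    total += math.exp(lp)
            return
        tail = int(col[idx + 1:].sum())
        for c in range(max(0, remaining - tail), min(col[idx], remaining) + 1):
            rec(idx + 1, remaining - c, cells + [c])

    rec(0, r0, [])
    return min(total, 1.0)


def covariate_table(
    cohort: pd.DataFrame,
    covariates: dict[str, str],
    outcome: str = "vad_status",
) -> list[CovariateTestResult]:
    """Covariate-by-outcome association table.

    ``covariates`` maps column name -> "continuous" | "categorical".
    Continuous covariates are compared between the two outcome groups by
    Welch's t-test; categorical ones by Fisher's exact test (exact
    conditional enumeration for 2 x k tables with total <= 500, chi-square
    otherwise).  Group summaries (mean/SD or counts/%) are echoed.  Constant
    covariates are skipped with a log entry.
    """
    if outcome not in cohort.columns:
        raise KeyError(f"outcome column {outcome!r} not in cohort")
    levels = [lv for lv in cohort[outcome].dropna().unique()]
    if len(levels) != 2:
        raise ValueError(f"outcome must have two non-empty levels, got {levels}")
    g1 = cohort[cohort[outcome] == levels[0]]
    g2 = cohort[cohort[outcome] == levels[1]]
    results: list[CovariateTestResult] = []
    for col, kind in covariates.items():
        if col not in cohort.columns:
            raise KeyError(f"covariate column {col!r} not in cohort")
        if kind == "continuous":
            x = pd.to_numeric(g1[col], errors="coerce").dropna()
            y = pd.to_numeric(g2[col], errors="coerce").dropna()
            if x.nunique() <= 1 and y.nunique() <= 1 and set(x.unique()) == set(y.unique()):
                logger.warning("constant continuous covariate %s skipped", col)
                continue
            t = stats.ttest_ind(x, y, equal_var=False)
            results.append(
                CovariateTestResult(
                    covariate=col, kind=kind,
                    statistic=float(t.statistic), p_value=float(t.pvalue),
                    summaries={
                        str(levels[0]): {"mean": float(x.mean()), "sd": float(x.std())},
                        str(levels[1]): {"mean": float(y.mean()), "sd": float(y.std())},
                    },
                    test="welch_t",
                )
            )
        elif kind == "categorical":
            sub = cohort[[col, outcome]].dropna()
            ct = pd.crosstab(sub[outcome], sub[col])
            if ct.shape[1] < 2:
                logger.warning("constant categorical covariate %s skipped", col)
                continue
            counts = ct.to_numpy()
            if counts.shape == (2, 2):
                p = float(stats.fisher_exact(counts).pvalue)
                test = "fisher_exact"
            elif counts.sum() <= 500:
                p = _exact_2xk_p(counts)
                test = "exact_2xk"
            else:
                p = float(stats.chi2_contingency(counts).pvalue)
                test = "chi2"
            pct = ct.div(ct.sum(axis=1), axis=0) * 100
            results.append(
                CovariateTestResult(
                    covariate=col, kind=kind, statistic=float("nan"), p_value=p,
                    summaries={
                        "counts": ct.to_dict(), "percent": pct.round(1).to_dict()
                    },
                    test=test,
                )
            )
        else:
            raise ValueError(f"covariate kind must be continuous|categorical, got {kind!r}")
    return results


def who_supplementation_flag(
    cohort: pd.DataFrame, thresholds: Thresholds = Thresholds()
):
    """Population-level supplementation trigger for pregnant women.

    Returns ``(flag, proportion)``: the proportion of pregnant records with
    retinol below ``severe_cutoff`` and whether it reaches ``who_trigger``
    (>= 20% by default).  Raises if no pregnant record with retinol exists.
    """
    preg = cohort[pd.to_numeric(cohort.get("pregnant"), errors="coerce") == 1]
    ret = pd.to_numeric(preg["retinol_umol_L"], errors="coerce").dropna()
    ret = ret[ret > 0]
    if ret.empty:
        raise ValueError("no pregnant records with serum retinol available")
    prop = float((ret < thresholds.severe_cutoff).mean())
    return prop >= thresholds.who_trigger, prop
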