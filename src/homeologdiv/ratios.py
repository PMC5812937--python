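"""Homeolog expression-ratio statistics.

The expression ratio of an A:B homeolog pair in a sample group is
r = avgRPKM_A / (avgRPKM_A + avgRPKM_B), with the averages taken over the
group's replicates; r = 0.5 means balanced expression, r >= 0.6 or r <= 0.4
is categorized as unbalanced.  Group-level summaries report the usual
descriptives plus the counts of pairs with the A member strictly higher
(Ab) or the B member strictly higher (aB), a Bonferroni-adjusted two-sided
exact binomial test of Ab = aB, and the percentage of unbalanced pairs.
Between-condition widening of the ratio distribution is tested with the
Fligner-Killeen rank test of variance homogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_ratio_table",
    "RatioTableResult",
    "GroupSummary",
    "summarize_group",
    "adjusted_binomial_pvalue",
    "variance_divergence_test",
    "skewness",
    "classify_balance",
]

UNBALANCED_LOW = 0.4
UNBALANCED_HIGH = 0.6


def classify_balance(ratio: float, low: float = UNBALANCED_LOW,
                     high: float = UNBALANCED_HIGH) -> str:
    """Inclusive thresholds: <=low is B-dominant, >=high is A-dominant."""
    if np.isnan(ratio):
        return "undefined"
    if ratio >= high:
        return "unbalanced_A"
    if ratio <= low:
        return "unbalanced_B"
    return "balanced"


def _a_share(avg_a: float, avg_b: float) -> float:
    """A/(A+B) computed so that swapping A and B complements it exactly.

    The smaller member is divided and the larger obtained as 1 minus that
    quotient, which makes r(A, B) + r(B, A) == 1 hold bit-exactly in IEEE
    arithmetic (the plain two-division form misses by one ulp for ~15% of
    inputs).  Undefined (NaN) when both averages are zero.
    """
    denom = avg_a + avg_b
    if denom <= 0:
        return float("nan")
    if avg_a <= avg_b:
        return avg_a / denom
    return 1.0 - avg_b / denom


@dataclass
class RatioTableResult:
    """Ratio table plus the exclusion bookkeeping of its construction."""

    table: pd.DataFrame
    n_pairs_input: int
    n_pairs_excluded_no_evidence: int  # neither homeolog ever expressed
    n_pairs_single_expressed: int      # exactly one homeolog ever expressed


def build_ratio_table(
    rpkm: pd.DataFrame,
    design: pd.DataFrame,
    pairs: list[tuple[str, str]],
    evidence: pd.DataFrame | None = None,
    thresholds: tuple[float, float] = (UNBALANCED_LOW, UNBALANCED_HIGH),
) -> RatioTableResult:
    """One row per (pair, condition x timepoint group) with the A-share ratio.

    Replicate RPKM values are arithmetically averaged within each group.
    Pairs in which neither homeolog shows evidence of expression in either
    condition are excluded from the table entirely; a group in which both
    averages are zero yields an undefined ratio for that group only.
    """
    known = set(rpkm.index)
    for a, b in pairs:
        if a not in known or b not in known:
            raise ValueError(f"pair ({a}, {b}) references genes absent from "
                             "the RPKM matrix")
    low, high = thresholds

    expressed_any = None
    if evidence is not None:
        exp_cols = [c for c in evidence.columns if c.startswith("expressed_")]
        expressed_any = evidence[exp_cols].any(axis=1)

    groups = (
        design.reset_index()
        .groupby(["condition", "timepoint"], sort=False)["sample_id"]
        .apply(list)
    )

    rows = []
    n_excluded = n_single = 0
    for i, (a, b) in enumerate(pairs):
        if expressed_any is not None:
            ea, eb = bool(expressed_any.get(a, False)), bool(expressed_any.get(b, False))
            if not ea and not eb:
                n_excluded += 1
                continue
            if ea != eb:
                n_single += 1
        for (cond, tp), samples in groups.items():
            avg_a = float(rpkm.loc[a, samples].mean())
            avg_b = float(rpkm.loc[b, samples].mean())
            ratio = _a_share(avg_a, avg_b)
            rows.append({
                "pair_id": f"PAIR{i + 1:05d}",
                "gene_id_A": a, "gene_id_B": b,
                "condition": cond, "timepoint": tp,
                "avg_rpkm_A": avg_a, "avg_rpkm_B": avg_b,
                "ratio": ratio,
                "balance": classify_balance(ratio, low, high),
            })
    table = pd.DataFrame(rows, columns=[
        "pair_id", "gene_id_A", "gene_id_B", "condition", "timepoint",
        "avg_rpkm_A", "avg_rpkm_B", "ratio", "balance"])
    return RatioTableResult(
        table=table,
        n_pairs_input=len(pairs),
        n_pairs_excluded_no_evidence=n_excluded,
        n_pairs_single_expressed=n_single,
    )


def adjusted_binomial_pvalue(n_ab: int, n_ab_other: int,
                             family_size: int = 4) -> float:
    """Bonferroni-adjusted two-sided exact binomial P for Ab = aB.

    Two-sided by the minimum-likelihood convention: sum of the
    probabilities of all outcomes no more likely than the observed one,
    under Binomial(n_ab + n_ab_other, 1/2).
    """
    if n_ab < 0 or n_ab_other < 0:
        raise ValueError("counts must be nonnegative")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    n = n_ab + n_ab_other
    if n == 0:
        return 1.0
    p = stats.binomtest(n_ab, n, 0.5, alternative="two-sided").pvalue
    return min(1.0, family_size * p)


def skewness(values, estimator: str = "type3") -> float:
    """Moment skewness with the three standard small-sample estimators.

    type1: g1 = m3 / m2^{3/2} (plain moment ratio)
    type2: G1 = g1 * sqrt(n(n-1)) / (n-2) (adjusted Fisher-Pearson)
    type3: b1 = g1 * ((n-1)/n)^{3/2} (the default of the descriptive-
    statistics convention this package follows)
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 3:
        raise ValueError("skewness needs at least 3 values")
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        raise ValueError("skewness undefined for a constant vector")
    g1 = np.mean((x - x.mean()) ** 3) / m2 ** 1.5
    if estimator == "type1":
        return float(g1)
    if estimator == "type2":
        if n < 3:
            raise ValueError("type2 skewness needs n >= 3")
        return float(g1 * np.sqrt(n * (n - 1)) / (n - 2))
    if estimator == "type3":
        return float(g1 * ((n - 1) / n) ** 1.5)
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class GroupSummary:
    """Descriptives and tests of one group's ratio distribution."""

    group: str
    n_pairs: int
    n_undefined: int
    mean: float
    median: float
    sd: float
    skew: float
    n_Ab: int
    n_aB: int
    n_ties: int
    binom_p_adjusted: float
    pct_unbalanced: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_group(
    ratios,
    group: str = "",
    family_size: int = 4,
    thresholds: tuple[float, float] = (UNBALANCED_LOW, UNBALANCED_HIGH),
    skew_estimator: str = "type3",
) -> GroupSummary:
    """Summarize one group's ratio vector (NaN = undefined, dropped).

    Ab / aB count pairs with ratio strictly above / below 0.5; exact ties
    at 0.5 count toward neither and are reported in ``n_ties``.
    """
    x = np.asarray(ratios, dtype=float)
    n_undef = int(np.isnan(x).sum())
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no defined ratios in group")
    low, high = thresholds
    n_ab = int((x > 0.5).sum())
    n_ab_other = int((x < 0.5).sum())
    n_unbal = int(((x <= low) | (x >= high)).sum())
    return GroupSummary(
        group=group,
        n_pairs=int(x.size),
        n_undefined=n_undef,
        mean=float(x.mean()),
        median=float(np.median(x)),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        skew=skewness(x, skew_estimator) if x.size >= 3 and x.std() > 0 else 0.0,
        n_Ab=n_ab,
        n_aB=n_ab_other,
        n_ties=int(x.size - n_ab - n_ab_other),
        binom_p_adjusted=adjusted_binomial_pvalue(n_ab, n_ab_other, family_size),
        pct_unbalanced=100.0 * n_unbal / x.size,
    )


def variance_divergence_test(
    ratios_condition1, ratios_condition2
) -> tuple[float, float]:
    """Fligner-Killeen test of equal ratio variance between two groups.

    Median-centered, normal-scores-weighted rank test; returns the
    chi-squared statistic and its upper-tail P value.  NaNs are dropped.
    """
    x = np.asarray(ratios_condition1, dtype=float)
    y = np.asarray(ratios_condition2, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 defined ratios")
    stat, p = stats.fligner(x, y)
    return float(stat), float(p)


def summarize_ratio_table(
    table: pd.DataFrame,
    family_size: int = 4,
    thresholds: tuple[float, float] = (UNBALANCED_LOW, UNBALANCED_HIGH),
) -> list[GroupSummary]:
    """One GroupSummary per (condition, timepoint) group of a ratio table."""
    out = []
    for (cond, tp), sub in table.groupby(["condition", "timepoint"], sort=False):
        out.append(summarize_group(
            sub["ratio"].values, group=f"{cond}_{tp}",
            family_size=family_size, thresholds=thresholds))
    return out
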