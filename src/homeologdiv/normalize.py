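"""Between-sample normalization (TMM scaling factors, CPM, RPKM) and the
expression-evidence filter.

TMM (trimmed mean of M-values) estimates one scaling factor per sample from
doubly trimmed, precision-weighted log-ratios against a reference sample;
factors are rescaled to geometric mean 1 and multiply the raw library sizes
into effective library sizes.  CPM divides counts by the effective library
size (per million); RPKM additionally divides by gene length (per kilobase).

A gene shows evidence of expression in a condition when at least
``min_samples`` of that condition's samples reach ``min_cpm``; the two
per-condition flags induce the four-way categorization expressed-in-both /
condition-specific (either direction) / no evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "tmm_factors",
    "effective_library_sizes",
    "cpm",
    "rpkm",
    "NormalizedExpression",
    "normalize_counts",
    "flag_expression",
    "category_counts",
]


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    totals = counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"samples with all-zero counts: {zero}")
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference.

    M = log2 relative expression, A = average log expression, computed over
    genes positive in both samples; the top/bottom trim_m of M and trim_a of
    A are dropped and the surviving M are averaged with inverse
    delta-method-variance weights.
    """
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    y_o, y_r = obs[pos], ref[pos]
    m = np.log2((y_o / n_obs) / (y_r / n_ref))
    a = 0.5 * np.log2((y_o / n_obs) * (y_r / n_ref))
    # binomial delta-method variance of M
    var = (n_obs - y_o) / (n_obs * y_o) + (n_ref - y_r) / (n_ref * y_r)

    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().values
    rank_a = pd.Series(a).rank().values
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    w = 1.0 / var[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    ``reference``: a sample id, or None to pick the sample whose
    75th-percentile count fraction is closest to the mean of those
    percentiles across samples.
    """
    _check_counts(counts)
    totals = counts.sum(axis=0).astype(float)
    if reference is None:
        frac75 = counts.apply(lambda col: np.percentile(col, 75)) / totals
        reference = (frac75 - frac75.mean()).abs().idxmin()
    elif reference not in counts.columns:
        raise ValueError(f"reference sample {reference!r} not in matrix")

    ref = counts[reference].values.astype(float)
    n_ref = totals[reference]
    raw = pd.Series(
        {
            s: 1.0 if s == reference else _tmm_pair(
                counts[s].values.astype(float), ref, totals[s], n_ref,
                trim_m, trim_a)
            for s in counts.columns
        }
    )
    return raw / np.exp(np.log(raw).mean())


def effective_library_sizes(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    return counts.sum(axis=0).astype(float) * factors


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million of effective library size (factors=None: raw)."""
    eff = counts.sum(axis=0).astype(float)
    if factors is not None:
        eff = eff * factors.reindex(counts.columns)
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    return counts / eff * 1e6


def rpkm(counts: pd.DataFrame, factors: pd.Series | None,
         lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million: CPM scaled by 1e3 / gene length."""
    lens = lengths.reindex(counts.index)
    if lens.isna().any():
        missing = lens.index[lens.isna()].tolist()
        raise ValueError(f"genes without length: {missing[:5]}")
    if (lens <= 0).any():
        raise ValueError("gene lengths must be positive")
    return cpm(counts, factors).mul(1e3 / lens, axis=0)


@dataclass
class NormalizedExpression:
    """TMM factors, effective sizes and the CPM / RPKM matrices."""

    tmm_factors: pd.Series
    effective_library_sizes: pd.Series
    cpm: pd.DataFrame
    rpkm: pd.DataFrame


def normalize_counts(
    counts: pd.DataFrame,
    lengths: pd.Series,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    reference: str | None = None,
    use_effective_sizes: bool = True,
) -> NormalizedExpression:
    """One-call TMM + CPM + RPKM. ``use_effective_sizes=False`` computes
    CPM/RPKM on raw library sizes while still reporting the factors."""
    factors = tmm_factors(counts, trim_m=trim_m, trim_a=trim_a,
                          reference=reference)
    f = factors if use_effective_sizes else None
    return NormalizedExpression(
        tmm_factors=factors,
        effective_library_sizes=effective_library_sizes(counts, factors),
        cpm=cpm(counts, f),
        rpkm=rpkm(counts, f, lengths),
    )


def flag_expression(
    cpm_matrix: pd.DataFrame,
    design: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 3,
    pool_timepoints: bool = True,
) -> pd.DataFrame:
    """Per-gene expression evidence and category.

    design: sample-indexed DataFrame with ``condition`` (and ``timepoint``)
    columns; exactly two conditions.  With ``pool_timepoints`` (default) the
    evidence unit is the condition, pooling its time points; otherwise every
    (condition, timepoint) group must independently reach the threshold and
    a condition counts as expressed if any of its groups does.
    """
    conditions = list(dict.fromkeys(design["condition"]))
    if len(conditions) != 2:
        raise ValueError(f"exactly two conditions required, got {conditions}")
    missing = [s for s in design.index if s not in cpm_matrix.columns]
    if missing:
        raise ValueError(f"design samples missing from matrix: {missing}")

    flags = {}
    for cond in conditions:
        samples = design.index[design["condition"] == cond]
        if pool_timepoints:
            unit_sets = [samples]
        else:
            unit_sets = [
                design.index[(design["condition"] == cond)
                             & (design["timepoint"] == tp)]
                for tp in dict.fromkeys(design.loc[samples, "timepoint"])
            ]
        for unit in unit_sets:
            if len(unit) < min_samples:
                raise ValueError(
                    f"condition {cond!r} group has {len(unit)} samples, fewer "
                    f"than min_samples={min_samples}; lower min_samples"
                )
        per_unit = [
            (cpm_matrix[unit] >= min_cpm).sum(axis=1) >= min_samples
            for unit in unit_sets
        ]
        flags[cond] = np.logical_or.reduce(per_unit)

    c1, c2 = conditions
    ev = pd.DataFrame(
        {f"expressed_{c1}": flags[c1], f"expressed_{c2}": flags[c2]},
        index=cpm_matrix.index,
    )
    cat = np.select(
        [
            ev.iloc[:, 0] & ev.iloc[:, 1],
            ev.iloc[:, 0] & ~ev.iloc[:, 1],
            ~ev.iloc[:, 0] & ev.iloc[:, 1],
        ],
        ["expressed_both", f"{c1}_specific", f"{c2}_specific"],
        default="no_evidence",
    )
    ev["category"] = cat
    return ev


def category_counts(evidence: pd.DataFrame) -> pd.Series:
    """Gene tally per expression category (overview-table layout)."""
    order = [c for c in
             ["expressed_both"]
             + sorted(set(evidence["category"]) - {"expressed_both", "no_evidence"})
             + ["no_evidence"]]
    return evidence["category"].value_counts().reindex(order, fill_value=0)
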