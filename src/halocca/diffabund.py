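"""Two-population comparison of functional category proportions.

Mirrors the standard STAMP-style construction: per category, the difference
of mean proportions between two sample groups is tested with Welch's unequal-
variance t-test, a 95% confidence interval is built from the Welch–
Satterthwaite degrees of freedom, and p-values are Bonferroni-corrected over
the number of categories tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AbundanceMatrix, EnvTable

__all__ = [
    "GroupComparison",
    "welch_t",
    "bonferroni",
    "compare_groups",
    "comparisons_frame",
    "split_by_salinity",
]


@dataclass
class GroupComparison:
    """Welch/Bonferroni statistics for one category between groups A and B."""

    category: str
    mean_prop_a: float
    mean_prop_b: float
    diff: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p_raw: float
    p_bonferroni: float


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sided t-test: returns (t, Welch–Satterthwaite df, p).

    Both groups need at least two observations.  When both groups have zero
    variance the test is degenerate: equal means give (0, pooled df, 1);
    unequal means are an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni correction: min(1, m·p) with m = number of tests."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    return list(np.minimum(1.0, m * p))


def compare_groups(
    matrix: AbundanceMatrix,
    groups: Mapping[str, str],
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Per-category Welch comparison of proportions between groups "A" and "B".

    ``matrix`` must be in the ``proportions`` state; ``groups`` maps each
    sample id to "A" or "B" (samples absent from the mapping are ignored).
    The Bonferroni factor is the number of categories tested; output is
    sorted by raw p-value ascending, ties broken by category id.
    """
    if matrix.state != "proportions":
        raise ValueError(f"expected a proportions matrix, got state {matrix.state!r}")
    labels = {s: groups[s] for s in matrix.samples if s in groups}
    bad = sorted(set(labels.values()) - {"A", "B"})
    if bad:
        raise ValueError(f"group labels must be 'A' or 'B', got {bad}")
    a_samples = [s for s, g in labels.items() if g == "A"]
    b_samples = [s for s, g in labels.items() if g == "B"]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (A: {len(a_samples)}, B: {len(b_samples)})"
        )
    A = matrix.frame.loc[a_samples]
    B = matrix.frame.loc[b_samples]
    partial = []
    for cat in matrix.features:
        a = A[cat].to_numpy()
        b = B[cat].to_numpy()
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            t, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
            half = 0.0
        else:
            t, df, p = welch_t(a, b)
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            half = float(stats.t.ppf(1 - alpha / 2, df) * se)
        diff = float(a.mean() - b.mean())
        partial.append((cat, float(a.mean()), float(b.mean()), diff, half, t, df, p))
    p_corr = bonferroni([row[7] for row in partial])
    out = [
        GroupComparison(
            category=cat,
            mean_prop_a=ma,
            mean_prop_b=mb,
            diff=diff,
            ci_low=diff - half,
            ci_high=diff + half,
            t=t,
            df=df,
            p_raw=p,
            p_bonferroni=pc,
        )
        for (cat, ma, mb, diff, half, t, df, p), pc in zip(partial, p_corr)
    ]
    out.sort(key=lambda c: (c.p_raw, c.category))
    return out


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabular view of :func:`compare_groups` output."""
    return pd.DataFrame([vars(c) for c in comparisons])


def split_by_salinity(env: EnvTable, threshold_psu: float = 10.0) -> dict[str, str]:
    """Documented helper: label samples below ``threshold_psu`` as group "A"
    (brackish) and the rest as group "B" (marine).

    This mirrors the brackish-vs-marine split of low- and high-salinity
    populations; it is a labelling convenience, not an inference step.
    """
    sal = env.env["salinity"]
    return {s: ("A" if sal[s] < threshold_psu else "B") for s in env.samples}
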