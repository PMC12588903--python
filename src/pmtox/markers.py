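"""Univariate marker statistics and the VIP ∧ FDR selection rule.

A compound is flagged as a toxicity-related differential marker when it is
influential in the OPLS-DA projection (VIP > 1) *and* survives multiplicity
correction in the univariate test (Benjamini-Hochberg q < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerResult",
    "welch_t_test",
    "one_sample_t_test",
    "benjamini_hochberg",
    "select_markers",
    "one_way_anova_tukey",
    "duncan_mrt",
]


@dataclass(frozen=True)
class MarkerResult:
    compound_id: str
    vip: float
    t_statistic: float
    p_value: float
    q_value: float
    is_marker: bool


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sample Welch t-test (Satterthwaite df), two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def one_sample_t_test(values, popmean: float) -> tuple[float, float]:
    """One-sample t-test against a reference mean (two-sided)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    res = stats.ttest_1samp(v, popmean)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values, clipped at 1, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_markers(compound_ids: Sequence[str], vip, q,
                   t_statistics=None, p_values=None,
                   vip_threshold: float = 1.0, q_threshold: float = 0.05) -> list[MarkerResult]:
    """Flag compounds with VIP strictly above and q strictly below threshold.

    Results are sorted by VIP descending.
    """
    vip = np.asarray(vip, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (len(compound_ids) == vip.size == q.size):
        raise ValueError("compound_ids, vip and q must have equal length")
    t_statistics = np.full(vip.size, np.nan) if t_statistics is None else np.asarray(t_statistics, float)
    p_values = np.full(vip.size, np.nan) if p_values is None else np.asarray(p_values, float)
    results = [
        MarkerResult(
            compound_id=str(cid),
            vip=float(v),
            t_statistic=float(t),
            p_value=float(pv),
            q_value=float(qv),
            is_marker=bool(v > vip_threshold and qv < q_threshold),
        )
        for cid, v, t, pv, qv in zip(compound_ids, vip, t_statistics, p_values, q)
    ]
    results.sort(key=lambda r: r.vip, reverse=True)
    return results


def common_markers(*marker_lists: Sequence[MarkerResult]) -> list[str]:
    """Compounds flagged in every comparison (the cross-comparison rule).

    The study design flags a compound as a toxicity marker only when it
    passes the VIP ∧ FDR rule in each pairwise group comparison; requiring
    agreement across comparisons sharply suppresses chance flags that the FDR
    level tolerates within a single family of tests.
    """
    if not marker_lists:
        return []
    sets = [{m.compound_id for m in lst if m.is_marker} for lst in marker_lists]
    return sorted(set.intersection(*sets))


def one_way_anova_tukey(values, group_labels) -> dict:
    """One-way ANOVA with Tukey HSD adjusted pairwise comparisons.

    Returns ``{"f_statistic", "p_value", "pairwise"}`` where pairwise is a
    DataFrame of all group pairs with adjusted p-values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[labels == g] for g in groups]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least 2 values")
    f_stat, p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group_1": groups[i],
                    "group_2": groups[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adjusted": float(tukey.pvalue[i, j]),
                }
            )
    return {
        "f_statistic": float(f_stat),
        "p_value": float(p),
        "pairwise": pd.DataFrame(rows),
    }


def duncan_mrt(values, group_labels, alpha: float = 0.05) -> pd.DataFrame:
    """Duncan's multiple range test on group means (optional post hoc).

    For means ranked ``r`` apart the critical range uses the studentized range
    at the stepwise protection level 1 - (1 - alpha)^(r - 1).  Returns each
    pair with its mean difference, critical range and significance flag.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()), key=str)
    samples = [values[labels == g] for g in groups]
    if len(groups) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    df_err = sum(s.size for s in samples) - len(groups)
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_err
    n_h = len(groups) / sum(1.0 / s.size for s in samples)  # harmonic mean size
    order = np.argsort([s.mean() for s in samples])
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            i, j = order[a], order[b]
            span = b - a + 1
            alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
            q_crit = stats.studentized_range.ppf(1.0 - alpha_p, span, df_err)
            critical = q_crit * np.sqrt(mse / n_h)
            diff = abs(samples[j].mean() - samples[i].mean())
            rows.append(
                {
                    "group_1": groups[i],
                    "group_2": groups[j],
                    "mean_diff": float(diff),
                    "critical_range": float(critical),
                    "significant": bool(diff > critical),
                }
            )
    return pd.DataFrame(rows)
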