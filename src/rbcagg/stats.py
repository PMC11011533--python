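"""Group comparisons and the relative-difference arithmetic on group means.

Two kinds of statements are supported: nonparametric hypothesis tests
between patient groups (rank-sum for independent groups, with an exact
small-sample null by full enumeration; a paired signed-rank variant for the
treated/untreated design; Pearson correlation), and the percent / fold
relations between published group means (e.g. "higher by 26%", "twice as
large") with presentation rounding kept separate from the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "RankSumResult",
    "percent_change",
    "reduction_percent",
    "fold_change",
    "format_percent",
    "format_fold",
    "rank_sum_exact_p",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "pearson_r",
    "holm_adjust",
    "compare_groups",
    "reproduce_table_relations",
    "PATIENT_RELATIONS",
    "OXIDATION_RELATIONS",
]

#: combined sample size at or below which the rank-sum null is enumerated
#: exactly.  15 covers every pairing of the study's group sizes (8, 7, 6),
#: so all between-group p-values are exact small-sample values; C(15,8) =
#: 6435 assignments is still instantaneous.
EXACT_ENUMERATION_LIMIT = 15


# --------------------------------------------------------------------------
# Percent / fold arithmetic
# --------------------------------------------------------------------------

def percent_change(mean_ref: float, mean_new: float) -> float:
    """Signed percent change of ``mean_new`` relative to ``mean_ref``."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return (mean_new / mean_ref - 1.0) * 100.0


def reduction_percent(mean_low_shear: float, mean_high_shear: float) -> float:
    """Percent reduction from the low-shear to the high-shear value."""
    if mean_low_shear <= 0:
        raise ValueError("low-shear mean must be positive")
    return (1.0 - mean_high_shear / mean_low_shear) * 100.0


def fold_change(mean_ref: float, mean_new: float) -> float:
    """Ratio ``mean_new / mean_ref``."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return mean_new / mean_ref


def format_percent(value: float) -> str:
    """Presentation rounding for percents: nearest integer."""
    return f"{round(abs(value))}%"


def format_fold(value: float) -> str:
    """Presentation rounding for fold changes: one decimal."""
    return f"{value:.1f}x"


# --------------------------------------------------------------------------
# Rank-sum (Mann–Whitney) test
# --------------------------------------------------------------------------

@dataclass
class RankSumResult:
    statistic_W: float  # rank sum of the first group
    p_value: float
    significant: bool
    alpha: float
    method: str  # "exact" or "asymptotic"
    all_tied: bool = False


def rank_sum_exact_p(values_a, values_b) -> float:
    """Two-sided exact rank-sum p-value by full enumeration.

    All C(n, n_a) assignments of the pooled mid-ranks to group a are
    enumerated; the p-value is the fraction whose rank sum deviates from its
    null mean at least as much as the observed one.  Ties are mid-ranked, so
    the enumeration remains exact in their presence.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, n = len(a), len(a) + len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    w_obs = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    d_obs = abs(w_obs - mu)
    hits = 0
    for idx in combinations(range(n), na):
        if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / comb(n, na)


def wilcoxon_rank_sum(values_a, values_b, alpha: float = 0.05, method: str = "auto") -> RankSumResult:
    """Two-sided rank-sum test between two independent groups.

    With ``method="auto"``, the null distribution is enumerated exactly for
    combined n ≤ 15 (ties mid-ranked) and approximated normally with tie and
    continuity correction otherwise.  Significance is declared at
    ``p ≤ alpha``.  When every value in both groups is identical the test is
    vacuous: p = 1 with ``all_tied`` set.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[: len(a)].sum())
    all_tied = len(np.unique(np.concatenate([a, b]))) == 1
    if all_tied:
        return RankSumResult(w, 1.0, False, alpha, "degenerate", all_tied=True)
    if method == "auto":
        method = "exact" if len(a) + len(b) <= EXACT_ENUMERATION_LIMIT else "asymptotic"
    if method == "exact":
        p = rank_sum_exact_p(a, b)
    elif method == "asymptotic":
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    p = min(p, 1.0)
    return RankSumResult(w, p, p <= alpha, alpha, method)


def wilcoxon_signed_rank(values_before, values_after, alpha: float = 0.05) -> RankSumResult:
    """Paired two-sided signed-rank test (same donors, treated vs untreated)."""
    a = np.asarray(values_before, dtype=float)
    b = np.asarray(values_after, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired test needs equal-length vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    if np.allclose(a, b):
        return RankSumResult(0.0, 1.0, False, alpha, "degenerate", all_tied=True)
    res = sps.wilcoxon(a, b, alternative="two-sided")
    p = float(res.pvalue)
    return RankSumResult(float(res.statistic), p, p <= alpha, alpha, "signed-rank")


# --------------------------------------------------------------------------
# Correlation
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    variable_x: str
    variable_y: str
    r: float
    p_value: float
    n: int


def pearson_r(x, y, variable_x: str = "x", variable_y: str = "y") -> CorrelationResult:
    """Pearson product-moment correlation with the t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    for name, v in ((variable_x, x), (variable_y, y)):
        if np.std(v) == 0:
            raise ValueError(f"variable {name!r} has zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(variable_x, variable_y, float(r), float(p), len(x))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


# --------------------------------------------------------------------------
# Group comparison records
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    metric_name: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    percent_change: float
    fold_change: float
    p_value: float
    significant: bool


def compare_groups(
    metric_name: str,
    group_a: str,
    values_a,
    group_b: str,
    values_b,
    alpha: float = 0.05,
    paired: bool = False,
) -> GroupComparison:
    """Build a full comparison record for one metric between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    res = (
        wilcoxon_signed_rank(a, b, alpha) if paired else wilcoxon_rank_sum(a, b, alpha)
    )
    mean_a = float(a.mean())
    mean_b = float(b.mean())
    fold = mean_b / mean_a if mean_a > 0 else float("nan")
    return GroupComparison(
        metric_name=metric_name,
        group_a=group_a,
        group_b=group_b,
        mean_a=mean_a,
        sd_a=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        n_a=len(a),
        mean_b=mean_b,
        sd_b=float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        n_b=len(b),
        percent_change=(fold - 1.0) * 100.0 if mean_a > 0 else float("nan"),
        fold_change=fold,
        p_value=res.p_value,
        significant=res.significant,
    )


# --------------------------------------------------------------------------
# Published-table relations
# --------------------------------------------------------------------------

#: Each relation: (name, kind, metric, reference group, comparison group).
#: kind "percent"  → percent_change(ref, new), presented as an integer %;
#: kind "fold"     → fold_change(ref, new), presented to one decimal;
#: kind "shear_reduction" → reduction from the metric's low- to high-shear
#: column within the reference group's row.
PATIENT_RELATIONS = [
    ("AI_L non-severe PE vs control", "percent", "AI_L", "control", "non_severe_pe"),
    ("AI_L severe PE vs control", "percent", "AI_L", "control", "severe_pe"),
    ("AI_L severe vs non-severe PE", "percent", "AI_L", "non_severe_pe", "severe_pe"),
    ("NA_L severe vs non-severe PE", "percent", "NA_L", "non_severe_pe", "severe_pe"),
    ("NA_L non-severe PE vs control", "percent", "NA_L", "control", "non_severe_pe"),
    ("AI high- vs low-shear reduction, control", "shear_reduction", "AI", "control", None),
    ("NA high- vs low-shear reduction, control", "shear_reduction", "NA", "control", None),
    ("NA_H non-severe PE vs control", "percent", "NA_H", "control", "non_severe_pe"),
    ("AI_H severe PE vs control", "fold", "AI_H", "control", "severe_pe"),
    ("NA_H severe PE vs control", "fold", "NA_H", "control", "severe_pe"),
]

OXIDATION_RELATIONS = [
    ("AI_L 200 mM H2O2 vs untreated", "percent", "AI_L", "untreated", "h2o2_200mM"),
    ("AI_L 300 mM H2O2 vs untreated", "percent", "AI_L", "untreated", "h2o2_300mM"),
    ("AI_L 400 mM H2O2 vs untreated", "fold", "AI_L", "untreated", "h2o2_400mM"),
    ("NA_L untreated vs 400 mM H2O2", "fold", "NA_L", "h2o2_400mM", "untreated"),
    ("AI_H 200 mM H2O2 vs untreated", "percent", "AI_H", "untreated", "h2o2_200mM"),
]

_METRIC_COLUMNS = ("AI_L", "NA_L", "AI_H", "NA_H")


def _cell(table: pd.DataFrame, group: str, metric: str) -> float:
    if group not in table.index:
        raise KeyError(f"group {group!r} missing from the means table")
    v = table.loc[group, metric]
    if pd.isna(v):
        raise KeyError(f"cell ({group!r}, {metric!r}) is missing")
    return float(v)


def reproduce_table_relations(table: pd.DataFrame, relations=None) -> pd.DataFrame:
    """Compute every narrative percent/fold relation from a group-means table.

    ``table`` is indexed by group label with columns AI_L, NA_L, AI_H, NA_H.
    ``relations`` defaults to the relation set matching the table's groups
    (patient groups or the oxidation series).  Returns a DataFrame with the
    raw value and the integer-percent / one-decimal-fold presentation.
    """
    for col in _METRIC_COLUMNS:
        if col not in table.columns:
            raise KeyError(f"means table is missing column {col!r}")
    if relations is None:
        if "control" in table.index:
            relations = PATIENT_RELATIONS
        elif "untreated" in table.index:
            relations = OXIDATION_RELATIONS
        else:
            raise KeyError(
                "cannot infer relation set: table has neither a 'control' "
                "nor an 'untreated' group"
            )
    rows = []
    for name, kind, metric, ref, new in relations:
        if kind == "percent":
            raw = percent_change(_cell(table, ref, metric), _cell(table, new, metric))
            present = format_percent(raw)
        elif kind == "fold":
            raw = fold_change(_cell(table, ref, metric), _cell(table, new, metric))
            present = format_fold(raw)
        elif kind == "shear_reduction":
            raw = reduction_percent(
                _cell(table, ref, f"{metric}_L"), _cell(table, ref, f"{metric}_H")
            )
            present = format_percent(raw)
        else:
            raise ValueError(f"unknown relation kind {kind!r}")
        rows.append(
            {
                "relation": name,
                "kind": kind,
                "metric": metric,
                "group_ref": ref,
                "group_new": new,
                "value": raw,
                "presentation": present,
            }
        )
    return pd.DataFrame(rows)
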