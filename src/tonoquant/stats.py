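"""Cell-size stratification and the nonparametric statistical battery.

Cells are pooled across all groups of an experiment and split into "small"
(below pooled median length) and "large" (above median) classes; with an odd
cell count the median cell joins the class containing its closest neighbor
by length.  Between-group comparisons use the Mann-Whitney U test (exact
enumeration for small tie-free samples), with Benjamini-Hochberg FDR
correction across the per-analysis family of comparisons, plus
Kruskal-Wallis with Dunn's post hoc, Welch's t-test, and two-way ANOVA
(type II) for the factorial designs.

Significance stars follow the reporting bands:
``**`` p <= 0.01, ``*`` 0.01 < p <= 0.05, ``(*)`` 0.05 < p <= 0.1,
``NS`` p >= 0.1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class CellMeasurement:
    """One analyzed quantity for one cell."""

    cell_id: str
    group_label: str
    length_um: float
    value: float

    def __post_init__(self) -> None:
        if not self.length_um > 0:
            raise ValueError("length_um must be positive")


def stars(p: float) -> str:
    """Significance annotation for an (adjusted) p-value."""
    if np.isnan(p):
        return "NA"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p < 0.1:
        return "(*)"
    return "NS"


# ---------------------------------------------------------------------------
# Size stratification


def classify_by_median(lengths: np.ndarray | list[float]) -> np.ndarray:
    """Small/large split about the pooled median length.

    Returns an array of ``"small"`` / ``"large"`` per cell (input order).
    Below-median cells are small, above-median cells large.  For an odd
    count, the cell providing the median joins the class containing its
    closest neighbor by length; an exactly equidistant neighbor pair breaks
    the tie toward "small".  All-equal lengths are a degenerate split.
    """
    lengths = np.asarray(lengths, dtype=float)
    n = len(lengths)
    if n < 2:
        raise ValueError("need at least 2 cells to split by median")
    if np.ptp(lengths) == 0:
        raise ValueError("degenerate split: all cell lengths are equal")
    order = np.argsort(lengths, kind="stable")
    out = np.empty(n, dtype=object)
    half = n // 2
    if n % 2 == 0:
        out[order[:half]] = "small"
        out[order[half:]] = "large"
    else:
        out[order[:half]] = "small"
        out[order[half + 1 :]] = "large"
        med_idx = order[half]
        below = lengths[order[half - 1]]
        above = lengths[order[half + 1]]
        med = lengths[med_idx]
        out[med_idx] = "small" if (med - below) <= (above - med) else "large"
    return out.astype(str)


# ---------------------------------------------------------------------------
# Tests


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when the combined sample size is <= 12 and there are
    no ties; tie-corrected normal approximation (with continuity correction)
    otherwise.  Returns ``(U of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    exact = len(combined) <= 12 and len(np.unique(combined)) == len(combined)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_dunn(groups: list[np.ndarray], labels: list[str] | None = None):
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post hoc (BH-corrected).

    Returns ``(H, omnibus_p, pairwise)`` where ``pairwise`` is a DataFrame
    with columns ``group_a, group_b, z, p_raw, p_adj, stars``.  Dunn's z
    statistics are computed on mean ranks of the pooled sample with the
    standard tie correction; two-sided normal p-values are BH-adjusted
    across all reported pairs.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if len(g) == 0:
            raise ValueError("all groups must be non-empty")
    labels = labels or [f"g{i}" for i in range(len(groups))]
    H, p_omni = sps.kruskal(*groups)

    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        ni, nj = len(groups[i]), len(groups[j])
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p_raw": p})
    pair = pd.DataFrame(rows)
    pair["p_adj"] = bh_adjust(pair["p_raw"].to_numpy())
    pair["stars"] = pair["p_adj"].map(stars)
    return float(H), float(p_omni), pair


def t_test(x, y) -> tuple[float, float]:
    """Welch two-sample t-test, two-sided; returns (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate variance in both samples")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def two_way_anova(values, factor_a, factor_b) -> dict[str, float]:
    """Two-way ANOVA with interaction, type II sums of squares.

    Returns p-values for factor A, factor B, and the A x B interaction.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "A": pd.Categorical(factor_a),
            "B": pd.Categorical(factor_b),
        }
    )
    model = ols("value ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "A": float(table.loc["C(A)", "PR(>F)"]),
        "B": float(table.loc["C(B)", "PR(>F)"]),
        "interaction": float(table.loc["C(A):C(B)", "PR(>F)"]),
    }


# ---------------------------------------------------------------------------
# Stratified comparison


def stratified_compare(
    measurements: list[CellMeasurement],
    metric_name: str = "value",
    split_by_median: bool = True,
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Between-group comparisons within small/large cell strata.

    All cells are pooled to find the median length split; within each size
    class every pair of groups is compared (Mann-Whitney by default, Welch
    t-test with ``test='ttest'``).  BH correction is applied across the
    whole family of comparisons of this call (one family per
    metric-by-stratification analysis).  Missing strata are reported with
    NaN p-values rather than failing.  Returns a tidy report with columns
    ``metric, stratum, group_a, group_b, n_a, n_b, test, statistic, p_raw,
    p_adj, stars``.
    """
    finite = [m for m in measurements if np.isfinite(m.value)]
    if len(finite) < 2:
        raise ValueError("need at least 2 finite measurements")
    if split_by_median:
        classes = classify_by_median([m.length_um for m in finite])
    else:
        classes = np.array(["all"] * len(finite))
    group_names = sorted({m.group_label for m in finite})
    rows = []
    for stratum in sorted(set(classes)):
        sel = [m for m, c in zip(finite, classes) if c == stratum]
        by_group = {
            g: np.array([m.value for m in sel if m.group_label == g])
            for g in group_names
        }
        for ga, gb in itertools.combinations(group_names, 2):
            a, b = by_group[ga], by_group[gb]
            row = {
                "metric": metric_name,
                "stratum": stratum,
                "group_a": ga,
                "group_b": gb,
                "n_a": len(a),
                "n_b": len(b),
                "test": test,
            }
            if len(a) == 0 or len(b) == 0 or (test == "ttest" and min(len(a), len(b)) < 2):
                row.update(statistic=np.nan, p_raw=np.nan)
            else:
                try:
                    if test == "mannwhitney":
                        stat, p = mann_whitney(a, b)
                    elif test == "ttest":
                        stat, p = t_test(a, b)
                    else:
                        raise ValueError(f"unknown test {test!r}")
                    row.update(statistic=stat, p_raw=p)
                except ValueError:
                    row.update(statistic=np.nan, p_raw=np.nan)
            rows.append(row)
    report = pd.DataFrame(rows)
    valid = report["p_raw"].notna()
    report["p_adj"] = np.nan
    if valid.any():
        report.loc[valid, "p_adj"] = bh_adjust(report.loc[valid, "p_raw"].to_numpy())
    report["stars"] = report["p_adj"].map(lambda p: stars(p) if pd.notna(p) else "NA")
    return report
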