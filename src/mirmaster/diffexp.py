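"""Two-group differential expression with BH correction.

Group conventions: log2 fold change is always group-of-interest mean minus
reference mean on already-log2 data, so a positive value means higher
expression in the group of interest (here, the mesenchymal subtype).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("mirmaster")

#: sample-size ceiling for the exact Mann-Whitney null (no ties)
_EXACT_WILCOXON_MAX_N = 12


def log2_fold_change(x, y) -> float:
    """mean(x) - mean(y) on log2-scale data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("log2_fold_change requires non-empty groups")
    return float(x.mean() - y.mean())


def welch_t_test(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided.

    Degenerate inputs follow the conventions: both groups constant with equal
    means -> (0, 1); constant with different means -> (inf sign, 0) and a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("welch_t_test requires >=2 observations per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        logger.warning("welch_t_test: zero-variance groups with different means; p=0 by convention")
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    stat, p = stats.ttest_ind(x, y, equal_var=False)
    return float(stat), float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Mann-Whitney-Wilcoxon test; U counts pairs (a < b) with a from ``x``.

    The null is exact (full enumeration) when n1+n2 <= 12 with no ties;
    otherwise normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_rank_sum requires non-empty groups")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= _EXACT_WILCOXON_MAX_N and no_ties) else "asymptotic"
    # scipy's U1 counts pairs x > y (+ half-ties); our orientation counts x < y,
    # which is scipy's U for the second sample.
    res = stats.mannwhitneyu(y, x, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression_table(
    m: ExpressionMatrix,
    group_mask,
    test: str = "welch_t",
) -> pd.DataFrame:
    """Per-feature two-group DE table with BH over all features jointly.

    ``group_mask`` marks the group of interest (mesenchymal) per sample, in
    the matrix's sample order. Columns: feature_id, log2fc, statistic,
    p_value, adj_p, test.
    """
    mask = np.asarray(group_mask, dtype=bool)
    if mask.size != m.n_samples:
        raise ValidationError(
            f"label mask length {mask.size} != number of samples {m.n_samples}"
        )
    if mask.all() or not mask.any():
        raise ValidationError("both classes must be non-empty")
    if test not in ("welch_t", "wilcoxon"):
        raise ValidationError(f"unknown test {test!r}; use welch_t or wilcoxon")

    a = m.values[:, mask]
    b = m.values[:, ~mask]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    if test == "welch_t":
        with np.errstate(divide="ignore", invalid="ignore"):
            stat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        stat = np.asarray(stat, dtype=float)
        p = np.asarray(p, dtype=float)
        degenerate = ~np.isfinite(p)
        if degenerate.any():  # constant rows: fall back to the scalar conventions
            for i in np.flatnonzero(degenerate):
                stat[i], p[i] = welch_t_test(a[i], b[i])
    else:
        res = stats.mannwhitneyu(b, a, axis=1, alternative="two-sided", method="asymptotic")
        stat = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    table = pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "log2fc": lfc,
            "statistic": stat,
            "p_value": np.clip(p, 0.0, 1.0),
            "adj_p": benjamini_hochberg(np.clip(p, 0.0, 1.0)),
            "test": test,
        }
    )
    return table


_RULES = ("less_than", "greater_than", "abs_greater_than")


def select_features(table: pd.DataFrame, lfc_rule: str, lfc_threshold: float,
                    fdr_ceiling: float) -> set[str]:
    """Ids passing a log2FC rule and an adjusted-p ceiling simultaneously."""
    if lfc_rule not in _RULES:
        raise ValidationError(f"unknown lfc_rule {lfc_rule!r}; use one of {_RULES}")
    lfc = table["log2fc"]
    if lfc_rule == "less_than":
        keep = lfc < lfc_threshold
    elif lfc_rule == "greater_than":
        keep = lfc > lfc_threshold
    else:
        keep = lfc.abs() > lfc_threshold
    keep &= table["adj_p"] < fdr_ceiling
    return set(table.loc[keep, "feature_id"])
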