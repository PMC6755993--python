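"""Direct-target triangulation and regulator-target correlation.

A gene is a prioritized direct-target candidate when it sits in the
regulator's inferred regulon, in the phenotype signature, and in every
supplied sequence-based prediction list (miRDB/TargetScan-style) for that
regulator — the three-way Venn intersection. The evidence table additionally
reports Pearson anticorrelation between regulator and gene expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg
from .io import ExpressionMatrix, TargetPredictionTable, ValidationError

logger = logging.getLogger("mirmaster")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_correlation needs >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def intersect_target_evidence(
    regulon,
    signature,
    predictions: list[TargetPredictionTable],
    regulator_id: str,
    gene_expr: ExpressionMatrix | None = None,
    mirna_expr: ExpressionMatrix | None = None,
    mode: str = "intersection",
) -> tuple[list[str], pd.DataFrame]:
    """Venn triangulation of direct-target evidence for one regulator.

    ``mode`` governs how the sequence-based sources combine: "intersection"
    (default: a gene must appear in every source) or "union". Returns the
    sorted prioritized gene list and the full evidence table over the union
    of all sources; when both expression matrices are given, per-gene
    Pearson r against the regulator is added with BH across the table.
    """
    if not predictions:
        raise ValidationError("at least one prediction source is required")
    if mode not in ("intersection", "union"):
        raise ValidationError("mode must be intersection or union")
    regulon = set(regulon)
    signature = set(signature)
    per_source = [set(p.predicted(regulator_id)) for p in predictions]
    if mode == "intersection":
        seq_support = set.intersection(*per_source) if per_source else set()
    else:
        seq_support = set.union(*per_source)
    prioritized = sorted(regulon & signature & seq_support)

    union = sorted(regulon | signature | set.union(*per_source))
    table = pd.DataFrame({
        "gene_id": union,
        "in_regulon": [g in regulon for g in union],
        "in_signature": [g in signature for g in union],
        "in_seq_predictions": [g in seq_support for g in union],
    })
    table["prioritized"] = table["gene_id"].isin(prioritized)

    if gene_expr is not None and mirna_expr is not None:
        if regulator_id not in mirna_expr.data.index:
            raise ValidationError(f"regulator {regulator_id} absent from miRNA matrix")
        x = mirna_expr.data.loc[regulator_id].to_numpy()
        rs, ps = [], []
        for g in union:
            if g in gene_expr.data.index:
                try:
                    r, p = pearson_correlation(x, gene_expr.data.loc[g].to_numpy())
                except ValidationError:
                    r, p = np.nan, np.nan
            else:
                r, p = np.nan, np.nan
            rs.append(r)
            ps.append(p)
        table["pearson_r"] = rs
        table["r_p_value"] = ps
        finite = table["r_p_value"].notna()
        adj = np.full(len(table), np.nan)
        if finite.any():
            adj[finite.to_numpy()] = benjamini_hochberg(table.loc[finite, "r_p_value"].to_numpy())
        table["r_adj_p"] = adj
    return prioritized, table
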