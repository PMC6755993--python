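"""Signed miRNA -> gene regulatory network inference.

Association is plug-in mutual information on equal-frequency (quantile) bins,
significance by regulator-wise sample-permutation with BH correction,
stability by bootstrap consensus, indirect-edge removal by the data
processing inequality (DPI) over regulator-regulator-target triangles, and
edge signs by Spearman correlation. Regulator-regulator MI is computed only
to adjudicate DPI triangles and never enters the final bipartite network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg, differential_expression_table, select_features
from .io import AnalysisConfig, ExpressionMatrix, ValidationError, znormalize

logger = logging.getLogger("mirmaster")


def default_n_bins(n: int) -> int:
    """Equal-frequency bin count B = clamp(floor(sqrt(n/5)), 2, 10)."""
    return int(np.clip(np.floor(np.sqrt(n / 5.0)), 2, 10))


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per observation; ties broken by stable rank."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * n_bins) // x.size


def _mi_from_bins(r_bins: np.ndarray, t_bins: np.ndarray, n_bins: int) -> np.ndarray:
    """MI (nats) of one binned regulator against each row of a binned matrix."""
    if t_bins.ndim == 1:
        t_bins = t_bins[None, :]
    G, n = t_bins.shape
    flat = (np.arange(G)[:, None] * n_bins + r_bins[None, :]) * n_bins + t_bins
    counts = np.bincount(flat.ravel(), minlength=G * n_bins * n_bins)
    counts = counts.reshape(G, n_bins, n_bins).astype(float)
    p = counts / n
    pr = p.sum(axis=2, keepdims=True)
    pt = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * (np.log(p) - np.log(pr) - np.log(pt))
    return np.where(np.isfinite(term), term, 0.0).sum(axis=(1, 2))


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Plug-in mutual information (nats) on equal-frequency bins.

    A constant vector yields 0 by convention (its single bin carries no
    information; zero-probability log terms are dropped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("mutual_information requires equal-length vectors")
    if x.size < 20:
        raise ValidationError("mutual_information requires n >= 20")
    b = n_bins if n_bins is not None else default_n_bins(x.size)
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return 0.0
    return float(_mi_from_bins(_quantile_bins(x, b), _quantile_bins(y, b)[None, :], b)[0])


@dataclass
class RegulatoryNetwork:
    """Bipartite signed regulator -> target network plus provenance."""

    edges: pd.DataFrame  # regulator_id, target_id, mi, perm_p, adj_p, bootstrap_support, sign, kept
    regulators: list[str]
    targets: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def kept_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["kept"]].reset_index(drop=True)

    def regulons(self) -> dict[str, dict[str, int]]:
        """regulator -> {target: sign} over kept edges."""
        out: dict[str, dict[str, int]] = {}
        for row in self.kept_edges.itertuples(index=False):
            out.setdefault(row.regulator_id, {})[row.target_id] = int(row.sign)
        return out

    def regulon(self, regulator_id: str) -> dict[str, int]:
        return self.regulons().get(regulator_id, {})


def permutation_pvalues(
    reg_values: np.ndarray,
    tgt_values: np.ndarray,
    n_permutations: int,
    seed: int,
    n_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed MI and permutation p per (regulator, target) pair.

    For each regulator the sample order is permuted ``n_permutations`` times
    and MI recomputed against every target, preserving the targets'
    correlation structure. perm_p = (1 + #{MI_perm >= MI_obs}) / (1 + n_perm).
    Returns (mi, perm_p), both shaped (R, G).
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    R, n = reg_values.shape
    G = tgt_values.shape[0]
    b = n_bins if n_bins is not None else default_n_bins(n)
    t_bins = np.stack([_quantile_bins(t, b) for t in tgt_values])
    r_bins = np.stack([_quantile_bins(r, b) for r in reg_values])
    mi = np.stack([_mi_from_bins(r_bins[i], t_bins, b) for i in range(R)])
    exceed = np.zeros((R, G), dtype=np.int64)
    for i in range(R):
        rb = r_bins[i]
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            exceed[i] += _mi_from_bins(rb[perm], t_bins, b) >= mi[i]
    perm_p = (1.0 + exceed) / (1.0 + n_permutations)
    return mi, perm_p


def bootstrap_support(
    reg_values: np.ndarray,
    tgt_values: np.ndarray,
    n_bootstraps: int,
    seed: int,
    alpha: float = 0.05,
    n_bins: int | None = None,
) -> np.ndarray:
    """Fraction of bootstrap resamples in which each pair clears that
    resample's MI significance cutoff.

    The per-resample cutoff is the (1 - alpha) quantile of a pooled
    permutation null (one sample-order permutation per regulator per
    resample). Returns support shaped (R, G).
    """
    if n_bootstraps < 10:
        raise ValidationError("n_bootstraps must be >= 10")
    rng = np.random.default_rng(seed)
    R, n = reg_values.shape
    G = tgt_values.shape[0]
    b = n_bins if n_bins is not None else default_n_bins(n)
    support = np.zeros((R, G))
    for _ in range(n_bootstraps):
        idx = rng.integers(0, n, size=n)
        rv = reg_values[:, idx]
        tv = tgt_values[:, idx]
        t_bins = np.stack([_quantile_bins(t, b) for t in tv])
        null_pool = []
        mi_rep = np.empty((R, G))
        for i in range(R):
            rb = _quantile_bins(rv[i], b)
            mi_rep[i] = _mi_from_bins(rb, t_bins, b)
            null_pool.append(_mi_from_bins(rb[rng.permutation(n)], t_bins, b))
        cutoff = np.quantile(np.concatenate(null_pool), 1.0 - alpha)
        support += mi_rep > cutoff
    return support / n_bootstraps


def dpi_filter(
    edges: pd.DataFrame,
    reg_reg_mi: pd.DataFrame,
    tolerance: float = 0.0,
) -> pd.DataFrame:
    """Data-processing-inequality pruning of regulator->target edges.

    For every triangle (R1-T, R2-T, R1-R2) the weakest of the three MI
    values is flagged when it falls below (1 - tolerance) times the smaller
    of the other two; flagged regulator->target edges are removed.
    Regulator-regulator associations are adjudication-only.
    """
    if not 0.0 <= tolerance <= 1.0:
        raise ValidationError("dpi tolerance must be in [0, 1]")
    edges = edges.copy()
    if edges.empty:
        return edges
    mi_lookup = {(r.regulator_id, r.target_id): r.mi for r in edges.itertuples(index=False)}
    by_target: dict[str, list[str]] = {}
    for (reg, tgt) in mi_lookup:
        by_target.setdefault(tgt, []).append(reg)
    removed: set[tuple[str, str]] = set()
    for tgt, regs in by_target.items():
        for r1, r2 in combinations(sorted(regs), 2):
            if r1 not in reg_reg_mi.index or r2 not in reg_reg_mi.columns:
                continue
            trio = {
                (r1, tgt): mi_lookup[(r1, tgt)],
                (r2, tgt): mi_lookup[(r2, tgt)],
                ("__rr__", "__rr__"): float(reg_reg_mi.loc[r1, r2]),
            }
            weakest = min(trio, key=trio.get)
            others = [v for k, v in trio.items() if k != weakest]
            if trio[weakest] < (1.0 - tolerance) * min(others):
                if weakest != ("__rr__", "__rr__"):
                    removed.add(weakest)
    if removed:
        logger.info("DPI removed %d of %d edges", len(removed), len(edges))
    keep_mask = [
        (r.regulator_id, r.target_id) not in removed for r in edges.itertuples(index=False)
    ]
    return edges[np.asarray(keep_mask)].reset_index(drop=True)


def assign_edge_signs(
    edges: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    method: str = "spearman",
) -> pd.DataFrame:
    """Sign each edge by the regulator-target rank correlation across samples.

    Zero correlation leaves the sign undefined; such edges are dropped with a
    warning. ``method`` is "spearman" (default, robust) or "pearson".
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError("sign method must be spearman or pearson")
    edges = edges.copy()
    if edges.empty:
        edges["sign"] = pd.Series(dtype=int)
        return edges
    signs = []
    for row in edges.itertuples(index=False):
        x = mirna_expr.data.loc[row.regulator_id].to_numpy()
        y = gene_expr.data.loc[row.target_id].to_numpy()
        if method == "spearman":
            r = stats.spearmanr(x, y).statistic
        else:
            r = stats.pearsonr(x, y).statistic
        signs.append(0 if (not np.isfinite(r) or r == 0) else int(np.sign(r)))
    edges["sign"] = signs
    undefined = edges["sign"] == 0
    if undefined.any():
        logger.warning("dropping %d edges with undefined sign (zero correlation)",
                       int(undefined.sum()))
    return edges[~undefined].reset_index(drop=True)


def infer_network(
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    group_mask,
    config: AnalysisConfig | None = None,
    regulators: list[str] | None = None,
    targets: list[str] | None = None,
) -> RegulatoryNetwork:
    """Full network-inference stage.

    Candidate regulators are miRNAs downregulated in the group of interest
    (log2FC < regulator_lfc_max at BH P < regulator_fdr) and candidate
    targets are genes with |log2FC| > target_abs_lfc_min at BH P <
    target_fdr, unless explicit candidate lists are supplied. Both matrices
    are independently z-normalized before integration. Pipeline: MI ->
    permutation BH filter (alpha = target_fdr) -> bootstrap consensus ->
    DPI -> signs.
    """
    cfg = config or AnalysisConfig()
    if list(gene_expr.sample_ids) != list(mirna_expr.sample_ids):
        raise ValidationError("gene and miRNA matrices must share ordered sample ids")
    mask = np.asarray(group_mask, dtype=bool)

    if regulators is None:
        mir_de = differential_expression_table(mirna_expr, mask, test="welch_t")
        regulators = sorted(
            select_features(mir_de, "less_than", cfg.regulator_lfc_max, cfg.regulator_fdr)
        )
    if targets is None:
        gene_de = differential_expression_table(gene_expr, mask, test="welch_t")
        targets = sorted(
            select_features(gene_de, "abs_greater_than", cfg.target_abs_lfc_min, cfg.target_fdr)
        )
    if not regulators:
        raise ValidationError(
            "no candidate regulator miRNA passed the downregulation filter; "
            "relax regulator_lfc_max/regulator_fdr or supply regulators explicitly"
        )
    if not targets:
        raise ValidationError(
            "no candidate target gene passed the differential-expression filter; "
            "relax target thresholds or supply targets explicitly"
        )
    logger.info("network inference: %d candidate regulators, %d candidate targets",
                len(regulators), len(targets))

    mir_z = znormalize(mirna_expr.subset_features(regulators))
    gene_z = znormalize(gene_expr.subset_features(targets))
    rv, tv = mir_z.values, gene_z.values
    n = rv.shape[1]
    b = default_n_bins(n)

    mi, perm_p = permutation_pvalues(rv, tv, cfg.n_permutations, cfg.rng_seed, n_bins=b)
    adj_p = benjamini_hochberg(perm_p.ravel()).reshape(perm_p.shape)
    significant = adj_p < cfg.target_fdr

    support = np.zeros_like(mi)
    if significant.any():
        support = bootstrap_support(rv, tv, cfg.n_bootstraps, cfg.rng_seed + 1,
                                    alpha=cfg.target_fdr, n_bins=b)
    consensus = significant & (support >= cfg.bootstrap_consensus)

    reg_idx, tgt_idx = np.nonzero(consensus)
    edges = pd.DataFrame(
        {
            "regulator_id": [regulators[i] for i in reg_idx],
            "target_id": [targets[j] for j in tgt_idx],
            "mi": mi[reg_idx, tgt_idx],
            "perm_p": perm_p[reg_idx, tgt_idx],
            "adj_p": adj_p[reg_idx, tgt_idx],
            "bootstrap_support": support[reg_idx, tgt_idx],
        }
    )

    # regulator-regulator MI, for DPI adjudication only
    rr = np.zeros((len(regulators), len(regulators)))
    r_bins = np.stack([_quantile_bins(r, b) for r in rv])
    for i in range(len(regulators)):
        rr[i] = _mi_from_bins(r_bins[i], r_bins, b)
    rr_df = pd.DataFrame(rr, index=regulators, columns=regulators)
    edges = dpi_filter(edges, rr_df, cfg.dpi_tolerance)
    edges = assign_edge_signs(edges, mir_z, gene_z)
    edges["kept"] = True
    edges = edges.sort_values(["regulator_id", "target_id"], kind="mergesort").reset_index(drop=True)
    logger.info("network inference kept %d edges", len(edges))
    return RegulatoryNetwork(
        edges=edges,
        regulators=list(regulators),
        targets=list(targets),
        provenance={
            "seed": cfg.rng_seed,
            "n_permutations": cfg.n_permutations,
            "n_bootstraps": cfg.n_bootstraps,
            "bootstrap_consensus": cfg.bootstrap_consensus,
            "dpi_tolerance": cfg.dpi_tolerance,
            "alpha": cfg.target_fdr,
            "n_bins": b,
        },
    )
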