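"""Preranked gene set enrichment analysis.

Genes are ranked by a score (here log2 fold change, mesenchymal vs rest) and
each set's enrichment score (ES) is the signed extremum of a weighted
Kolmogorov-Smirnov-like running sum: hits advance proportionally to
|score|^p, misses retreat uniformly. Null distributions come from gene
permutation (random hit positions), giving nominal p per set, NES by
same-sign null normalization and FDR q by the positive/negative-pool
convention of the original method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection, ValidationError

logger = logging.getLogger("mirmaster")


@dataclass
class RankedList:
    """Feature ids ordered by descending score; ties break lexicographically."""

    ids: list[str]
    scores: np.ndarray

    @classmethod
    def from_scores(cls, scores: pd.Series) -> "RankedList":
        df = scores.rename("score").rename_axis("id").reset_index()
        df = df.sort_values(["score", "id"], ascending=[False, True], kind="mergesort")
        return cls(df["id"].tolist(), df["score"].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.ids)


def _walk_es(scores: np.ndarray, hit_mask: np.ndarray, weight_p: float):
    """Running-sum ES for one hit pattern; returns (es, extremum index)."""
    n = scores.size
    n_hit = int(hit_mask.sum())
    w = np.abs(scores) ** weight_p
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores exactly zero: fall back to uniform steps
        hit_w = hit_mask.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~hit_mask) / (n - n_hit)
    walk = np.cumsum(steps)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i]), i


def enrichment_score(
    ranked: RankedList,
    gene_set,
    weight_p: float = 1.0,
) -> tuple[float, list[str]]:
    """ES and leading edge of one gene set against a ranked list.

    The leading edge holds member genes at or before the extremum for
    positive ES, and at or after it for negative ES.
    """
    members = set(gene_set)
    hit_mask = np.array([g in members for g in ranked.ids])
    if not hit_mask.any():
        raise ValidationError("gene set does not intersect the ranked list")
    if hit_mask.all():
        return 1.0, list(ranked.ids)
    es, i = _walk_es(ranked.scores, hit_mask, weight_p)
    if es >= 0:
        leading = [g for g, h in zip(ranked.ids[: i + 1], hit_mask[: i + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.ids[i:], hit_mask[i:]) if h]
    return es, leading


def _null_es(scores: np.ndarray, set_size: int, n_permutations: int,
             rng: np.random.Generator, weight_p: float) -> np.ndarray:
    """Gene-permutation null: ES of ``set_size`` random positions, repeated."""
    n = scores.size
    out = np.empty(n_permutations)
    hit = np.zeros(n, dtype=bool)
    for b in range(n_permutations):
        idx = rng.choice(n, size=set_size, replace=False)
        hit[:] = False
        hit[idx] = True
        out[b], _ = _walk_es(scores, hit, weight_p)
    return out


def gsea_run(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over a collection with a shared gene-permutation null.

    Sets are filtered to [min_size, max_size] members after intersection
    with the ranked list (skips logged). Columns: set_name, size, es, nes,
    nom_p, fdr_q, leading_edge.
    """
    if n_permutations < 100:
        logger.warning("GSEA with %d permutations; p-value resolution is coarse",
                       n_permutations)
    rng = np.random.default_rng(seed)
    present = set(ranked.ids)

    kept: list[tuple[str, int, float, list[str]]] = []
    for name in collection.names():
        members = collection.members(name) & present
        if not members:
            logger.warning("GSEA: set %s does not intersect the ranked list; skipped", name)
            continue
        if not (min_size <= len(members) <= max_size):
            logger.info("GSEA: set %s size %d outside [%d, %d]; skipped",
                        name, len(members), min_size, max_size)
            continue
        es, leading = enrichment_score(ranked, members, weight_p)
        kept.append((name, len(members), es, leading))
    if not kept:
        raise ValidationError("no gene set left after size filtering")

    # one shared null per distinct set size
    nulls = {size: _null_es(ranked.scores, size, n_permutations, rng, weight_p)
             for size in sorted({size for _, size, _, _ in kept})}

    rows = []
    all_null_nes: list[np.ndarray] = []
    obs_nes = []
    for name, size, es, leading in kept:
        null = nulls[size]
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        if es >= 0:
            same = null[null >= 0]
            nom_p = (1.0 + (same >= es).sum()) / (1.0 + same.size)
            nes = es / pos_mean if pos_mean else np.nan
        else:
            same = null[null < 0]
            nom_p = (1.0 + (same <= es).sum()) / (1.0 + same.size)
            nes = es / abs(neg_mean) if neg_mean else np.nan
        null_nes = np.where(null >= 0,
                            null / pos_mean if np.isfinite(pos_mean) else np.nan,
                            null / abs(neg_mean) if np.isfinite(neg_mean) else np.nan)
        all_null_nes.append(null_nes[np.isfinite(null_nes)])
        obs_nes.append(nes)
        rows.append({"set_name": name, "size": size, "es": es, "nes": nes,
                     "nom_p": nom_p, "leading_edge": leading})

    null_pool = np.concatenate(all_null_nes)
    obs = np.asarray(obs_nes, dtype=float)
    fdr = []
    for nes in obs:
        if not np.isfinite(nes):
            fdr.append(np.nan)
            continue
        if nes >= 0:
            null_frac_denom = (null_pool >= 0).sum()
            null_frac = (null_pool >= nes).sum() / null_frac_denom if null_frac_denom else 1.0
            obs_denom = (obs >= 0).sum()
            obs_frac = (obs >= nes).sum() / obs_denom if obs_denom else 1.0
        else:
            null_frac_denom = (null_pool < 0).sum()
            null_frac = (null_pool <= nes).sum() / null_frac_denom if null_frac_denom else 1.0
            obs_denom = (obs < 0).sum()
            obs_frac = (obs <= nes).sum() / obs_denom if obs_denom else 1.0
        fdr.append(min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0)

    table = pd.DataFrame(rows)
    table["fdr_q"] = fdr
    return table.sort_values(["fdr_q", "nom_p", "set_name"],
                             kind="mergesort").reset_index(drop=True)
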