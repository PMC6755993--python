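"""Master-regulator analysis.

Each regulator's regulon is tested for overrepresentation of a phenotype
signature (here, an EMT-like gene set) by an upper-tail hypergeometric test
within a fixed gene universe, BH-corrected across regulators. The coverage
metric ``proportion`` = (signature genes in the regulon) / (signature genes
in the universe) reproduces the significance-vs-coverage ranking view.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg
from .io import ValidationError

logger = logging.getLogger("mirmaster")


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValidationError(f"inconsistent hypergeometric arguments N={N} K={K} n={n} k={k}")
    if k > min(K, n):
        raise ValidationError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    # survival function at k-1; scipy evaluates in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def mra_enrichment(
    regulons: dict[str, set | dict],
    signature,
    universe,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each regulon for the signature.

    Regulons and the signature are intersected with the universe before
    counting; signature genes outside the universe are dropped (logged).
    Columns: regulator_id, N, K, n, k, p_value, adj_p, proportion.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    signature = set(signature)
    dropped = signature - universe
    if dropped:
        logger.info("MRA: %d signature genes outside the universe dropped", len(dropped))
    sig = signature & universe
    if not sig:
        raise ValidationError("signature has no genes in the universe")
    if not regulons:
        raise ValidationError("no regulons supplied")
    N, K = len(universe), len(sig)
    rows = []
    for reg in sorted(regulons):
        members = set(regulons[reg])
        regulon = members & universe
        n = len(regulon)
        k = len(regulon & sig)
        rows.append((reg, N, K, n, k, hypergeometric_tail(N, K, n, k), k / K))
    table = pd.DataFrame(rows, columns=["regulator_id", "N", "K", "n", "k",
                                        "p_value", "proportion"])
    table["adj_p"] = benjamini_hochberg(table["p_value"].to_numpy())
    return table[["regulator_id", "N", "K", "n", "k", "p_value", "adj_p", "proportion"]]


def rank_master_regulators(results: pd.DataFrame) -> pd.DataFrame:
    """Sort by adj_p ascending, ties by proportion descending then id.

    Adds ``neg_log10_adj_p`` for the significance-vs-coverage view.
    """
    if len(results) == 0:
        raise ValidationError("no MRA results to rank")
    out = results.copy()
    out["neg_log10_adj_p"] = -np.log10(out["adj_p"].clip(lower=np.finfo(float).tiny))
    out = out.sort_values(
        by=["adj_p", "proportion", "regulator_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out
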