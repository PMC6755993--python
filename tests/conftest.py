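import logging

import numpy as np
import pytest

from mirmaster.io import AnalysisConfig, TargetPredictionTable
from mirmaster.simulate import reduced_config, simulate_cohort

logging.getLogger("mirmaster").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def planted_cohort():
    """One desk-scale planted cohort shared by read-only tests."""
    return simulate_cohort(reduced_config(seed=11))


@pytest.fixture(scope="session")
def planted_network(planted_cohort):
    from mirmaster.network import infer_network

    return infer_network(
        planted_cohort.gene_expr,
        planted_cohort.mirna_expr,
        planted_cohort.mesenchymal_mask,
        AnalysisConfig(rng_seed=11),
    )


@pytest.fixture(scope="session")
def truth_predictions(planted_cohort):
    """Synthetic miRDB/TargetScan-like tables derived from the planted edges."""
    rng = np.random.default_rng(11)
    tables = []
    for name in ("mirdb_like", "targetscan_like"):
        mapping = {}
        for reg, sub in planted_cohort.truth.edges.groupby("regulator_id"):
            noise = rng.choice(planted_cohort.gene_expr.feature_ids, 20, replace=False)
            mapping[reg] = frozenset(set(sub["target_id"]) | set(noise))
        tables.append(TargetPredictionTable(name, mapping))
    return tables
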