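import numpy as np
import pandas as pd
import pytest

from mirmaster.io import AnalysisConfig, ValidationError
from mirmaster.network import (
    assign_edge_signs,
    bootstrap_support,
    default_n_bins,
    dpi_filter,
    infer_network,
    mutual_information,
    permutation_pvalues,
)
from mirmaster.simulate import null_config, simulate_cohort, truth_edge_list


class TestMutualInformation:
    def test_constant_vector_zero(self):
        assert mutual_information(np.ones(50), np.arange(50.0)) == 0.0

    def test_identity_two_bins_ln2(self):
        x = np.arange(1000.0)
        assert mutual_information(x, x, n_bins=2) == pytest.approx(np.log(2), abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=500), rng.normal(size=500)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x), abs=1e-12)

    def test_nonnegative_and_monotone_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = x + rng.normal(0, 0.5, 300)
        mi = mutual_information(x, y)
        assert mi >= 0
        # quantile binning: strictly increasing transforms leave MI unchanged
        assert mutual_information(np.exp(x), y ** 3 + 5 * y) == pytest.approx(
            mi, abs=1e-12)

    def test_null_below_permutation_quantile(self):
        """Independent pairs rarely exceed their own permutation null's 95th pct."""
        rng = np.random.default_rng(2)
        wins = 0
        for _ in range(50):
            x, y = rng.normal(size=1000), rng.normal(size=1000)
            mi = mutual_information(x, y)
            null = [mutual_information(rng.permutation(x), y) for _ in range(40)]
            wins += mi < np.quantile(null, 0.95)
        assert wins >= 45

    def test_short_vector_rejected(self):
        with pytest.raises(ValidationError):
            mutual_information(np.arange(10.0), np.arange(10.0))

    def test_default_bin_rule(self):
        assert default_n_bins(200) == 6
        assert default_n_bins(20) == 2
        assert default_n_bins(10_000) == 10


class TestPermutationPvalues:
    def test_perfect_dependence_attains_lower_bound(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 100))
        mi, p = permutation_pvalues(x, x.copy(), 100, seed=0)
        assert p[0, 0] == pytest.approx(1 / 101)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        r = rng.normal(size=(2, 80))
        t = rng.normal(size=(5, 80))
        _, p1 = permutation_pvalues(r, t, 100, seed=7)
        _, p2 = permutation_pvalues(r, t, 100, seed=7)
        np.testing.assert_array_equal(p1, p2)


class TestBootstrapSupport:
    def test_strong_edge_full_support(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, 200))
        y = x + rng.normal(0, 0.01, size=(1, 200))
        s = bootstrap_support(x, y, 20, seed=0)
        assert s[0, 0] == 1.0

    def test_support_bounded(self, planted_cohort):
        rng = np.random.default_rng(6)
        r = rng.normal(size=(2, 60))
        t = rng.normal(size=(4, 60))
        s = bootstrap_support(r, t, 10, seed=1)
        assert np.all((s >= 0) & (s <= 1))


class TestDPI:
    def _edges(self, rows):
        return pd.DataFrame(rows, columns=["regulator_id", "target_id", "mi"])

    def test_weakest_edge_removed(self):
        edges = self._edges([("R1", "T", 0.9), ("R2", "T", 0.5)])
        rr = pd.DataFrame([[0, 0.8], [0.8, 0]], index=["R1", "R2"],
                          columns=["R1", "R2"])
        out = dpi_filter(edges, rr, tolerance=0.0)
        assert list(out["regulator_id"]) == ["R1"]

    def test_tolerance_one_removes_nothing(self):
        edges = self._edges([("R1", "T", 0.9), ("R2", "T", 0.1)])
        rr = pd.DataFrame([[0, 0.8], [0.8, 0]], index=["R1", "R2"],
                          columns=["R1", "R2"])
        assert len(dpi_filter(edges, rr, tolerance=1.0)) == 2

    def test_strongest_edge_never_removed(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m1, m2, mrr = rng.random(3)
            edges = self._edges([("R1", "T", m1), ("R2", "T", m2)])
            rr = pd.DataFrame([[0, mrr], [mrr, 0]], index=["R1", "R2"],
                              columns=["R1", "R2"])
            out = dpi_filter(edges, rr, tolerance=0.0)
            strongest = "R1" if m1 >= m2 else "R2"
            if max(m1, m2) >= mrr:
                assert strongest in set(out["regulator_id"])


class TestSigns:
    def _em(self, arr, ids, kind):
        from mirmaster.io import ExpressionMatrix
        return ExpressionMatrix(pd.DataFrame(
            arr, index=ids, columns=[f"s{i}" for i in range(arr.shape[1])]), kind)

    def test_monotone_and_antimonotone(self):
        x = np.arange(30.0)[None, :]
        up = (2 * np.arange(30.0) + 1)[None, :]
        down = (-np.arange(30.0))[None, :]
        mir = self._em(x, ["R"], "mirna")
        gene = self._em(np.vstack([up, down]), ["T+", "T-"], "gene")
        edges = pd.DataFrame({"regulator_id": ["R", "R"], "target_id": ["T+", "T-"],
                              "mi": [1.0, 1.0]})
        out = assign_edge_signs(edges, mir, gene)
        assert dict(zip(out["target_id"], out["sign"])) == {"T+": 1, "T-": -1}


class TestInferNetwork:
    def test_planted_recovery_and_determinism(self, planted_cohort, planted_network):
        truth = truth_edge_list(planted_cohort.truth)
        true_pairs = set(zip(truth["regulator_id"], truth["target_id"]))
        kept = planted_network.kept_edges
        got = set(zip(kept["regulator_id"], kept["target_id"]))
        recall = len(got & true_pairs) / len(true_pairs)
        assert recall >= 0.8
        sign_map = dict(zip(zip(truth["regulator_id"], truth["target_id"]),
                            truth["sign"]))
        true_recovered = [(r, t) for r, t in got if (r, t) in sign_map]
        correct = sum(
            sign_map[(r, t)] == kept.set_index(["regulator_id", "target_id"])
            .loc[(r, t), "sign"]
            for r, t in true_recovered)
        assert correct / len(true_recovered) >= 0.95
        # determinism: rerun with the identical seed
        net2 = infer_network(planted_cohort.gene_expr, planted_cohort.mirna_expr,
                             planted_cohort.mesenchymal_mask,
                             AnalysisConfig(rng_seed=11))
        pd.testing.assert_frame_equal(planted_network.edges, net2.edges)

    def test_null_cohort_keeps_few_pairs(self):
        c = simulate_cohort(null_config(n_samples=150, n_genes=60, n_mirnas=8,
                                        regulon_size=15, signature_size=12,
                                        n_classifier_genes_planted=6, seed=21))
        net = infer_network(c.gene_expr, c.mirna_expr, c.mesenchymal_mask,
                            AnalysisConfig(n_permutations=200, rng_seed=21),
                            regulators=list(c.mirna_expr.feature_ids),
                            targets=list(c.gene_expr.feature_ids))
        assert len(net.kept_edges) / (8 * 60) <= 0.05

    def test_empty_candidates_informative(self, planted_cohort):
        with pytest.raises(ValidationError, match="regulator"):
            infer_network(planted_cohort.gene_expr, planted_cohort.mirna_expr,
                          planted_cohort.mesenchymal_mask,
                          AnalysisConfig(regulator_fdr=1e-300))

    def test_regulons_subset_of_targets(self, planted_network):
        for reg, regulon in planted_network.regulons().items():
            assert set(regulon) <= set(planted_network.targets)
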