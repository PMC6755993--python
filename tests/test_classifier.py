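import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mirmaster.classifier import (
    DEFAULT_DELTA_GRID,
    _discriminant,
    auc_mann_whitney,
    predict_nsc,
    train_nsc,
    two_step_feature_selection,
)
from mirmaster.io import AnalysisConfig, ExpressionMatrix, ValidationError, znormalize
from mirmaster.simulate import null_config, simulate_cohort


def _em(values, feature_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    feature_ids = feature_ids or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(
        values, index=feature_ids,
        columns=[f"s{i}" for i in range(values.shape[1])]))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 2, 3, 4, 5, 6],
                                [False] * 3 + [True] * 3) == 1.0

    def test_three_quarters(self):
        # positives (2, 4) vs negatives (1, 3): 3 of 4 pairs concordant
        assert auc_mann_whitney([1, 2, 3, 4],
                                [False, True, False, True]) == pytest.approx(0.75)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        mask = rng.random(30) < 0.4
        assert auc_mann_whitney(v, mask) == pytest.approx(
            1 - auc_mann_whitney(v, ~mask))

    def test_matches_sklearn_and_trapezoid(self):
        """Mann-Whitney AUC equals rank-based and trapezoidal ROC integration."""
        rng = np.random.default_rng(1)
        v = rng.normal(size=200)  # continuous: tie-free almost surely
        mask = rng.random(200) < 0.3
        ours = auc_mann_whitney(v, mask)
        assert ours == pytest.approx(roc_auc_score(mask, v), abs=1e-12)
        # trapezoidal integration over all thresholds
        thr = np.concatenate([[np.inf], np.sort(v)[::-1], [-np.inf]])
        tpr = [(v[mask] >= t).mean() for t in thr]
        fpr = [(v[~mask] >= t).mean() for t in thr]
        assert ours == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            auc_mann_whitney([1, 2], [True, True])


class TestTwoStepSelection:
    def test_planted_recovery(self, planted_cohort):
        z = znormalize(planted_cohort.gene_expr)
        sel = two_step_feature_selection(z, planted_cohort.mesenchymal_mask)
        assert sorted(sel) == planted_cohort.truth.classifier_gene_ids

    def test_null_cohort_errors(self):
        c = simulate_cohort(null_config(n_samples=100, n_genes=100, n_mirnas=10,
                                        regulon_size=30, seed=0))
        with pytest.raises(ValidationError):
            two_step_feature_selection(znormalize(c.gene_expr), c.mesenchymal_mask)

    def test_relaxed_auc_superset(self, planted_cohort):
        z = znormalize(planted_cohort.gene_expr)
        mask = planted_cohort.mesenchymal_mask
        strict = two_step_feature_selection(z, mask, AnalysisConfig())
        relaxed = two_step_feature_selection(
            z, mask, AnalysisConfig(auc_min=1e-9, n_classifier_genes=10_000))
        assert set(strict) <= set(relaxed)


class TestNSC:
    def test_no_shrinkage_centroids_equal_class_means(self):
        m = _em([[0.0, 0.1, -0.1, 5.0, 5.1, 4.9]])
        y = ["a"] * 3 + ["b"] * 3
        model = train_nsc(m, y, delta_grid=[0.0])
        np.testing.assert_allclose(model.shrunken_centroids[0],
                                   [0.0, 5.0], atol=1e-12)

    def test_full_shrinkage_predicts_largest_prior(self):
        rng = np.random.default_rng(2)
        m = _em(rng.normal(size=(3, 12)))
        y = ["big"] * 8 + ["small"] * 4
        model = train_nsc(m, y, delta_grid=[50.0])
        assert np.all(model.shrunken_deviations == 0)
        post = predict_nsc(model, m)
        assert (post["predicted"] == "big").all()

    def test_toy_discriminant_matches_direct_formula(self):
        """Two-class 2-gene toy: delta_k(x) recomputed from the definition."""
        a = np.array([[0, 0.2, -0.2, 2, 1.8, 2.2],
                      [0, -0.1, 0.1, 2, 2.1, 1.9]])
        m = _em(a)
        y = ["A"] * 3 + ["B"] * 3
        model = train_nsc(m, y, delta_grid=[0.0])
        x_star = np.array([[0.5], [1.0]])
        got = _discriminant(x_star, model.shrunken_centroids, model.pooled_sd,
                            model.s0, model.priors)[0]
        for k in range(2):
            expected = float(
                (((x_star[:, 0] - model.shrunken_centroids[:, k])
                  / (model.pooled_sd + model.s0)) ** 2).sum()
                - 2 * np.log(model.priors[k]))
            assert got[k] == pytest.approx(expected, abs=1e-9)

    def test_shrinkage_invariants(self):
        rng = np.random.default_rng(3)
        m = _em(rng.normal(size=(5, 40)))
        y = np.array(["A"] * 25 + ["B"] * 15)
        model = train_nsc(m, y, delta_grid=[0.3])
        # unshrunken deviations recomputed from the stored geometry
        counts = np.array([25, 15])
        m_k = np.sqrt(1 / counts - 1 / 40)
        denom = m_k[None, :] * (model.pooled_sd + model.s0)[:, None]
        d = (model.class_centroids - model.overall_centroid[:, None]) / denom
        assert np.all(np.abs(model.shrunken_deviations) <= np.abs(d) + 1e-12)
        assert np.all(model.shrunken_deviations[np.abs(d) <= 0.3] == 0)
        assert model.priors.sum() == pytest.approx(1.0)

    def test_small_class_rejected(self):
        m = _em(np.random.default_rng(0).normal(size=(2, 5)))
        with pytest.raises(ValidationError):
            train_nsc(m, ["A", "A", "A", "A", "B"])

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        m = _em(rng.normal(size=(4, 20)))
        y = ["A"] * 12 + ["B"] * 8
        model = train_nsc(m, y, delta_grid=[0.0, 0.5])
        model.to_json(tmp_path / "model.json")
        from mirmaster.classifier import ShrunkenCentroidModel
        back = ShrunkenCentroidModel.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(back.shrunken_centroids, model.shrunken_centroids)
        p1 = predict_nsc(model, m)
        p2 = predict_nsc(back, m)
        pd.testing.assert_frame_equal(p1, p2)

    def test_cv_reproducible(self):
        rng = np.random.default_rng(5)
        m = _em(rng.normal(size=(6, 60)) + np.r_[np.ones(30), np.zeros(30)][None, :])
        y = ["A"] * 30 + ["B"] * 30
        m1 = train_nsc(m, y, delta_grid=DEFAULT_DELTA_GRID, seed=9)
        m2 = train_nsc(m, y, delta_grid=DEFAULT_DELTA_GRID, seed=9)
        assert m1.delta == m2.delta


class TestPredict:
    def test_sample_at_centroid_gets_max_posterior(self):
        m = _em([[0.0, 0.2, -0.2, 3, 3.2, 2.8]])
        y = ["lo"] * 3 + ["hi"] * 3
        model = train_nsc(m, y, delta_grid=[0.0])
        test = _em([[0.0, 3.0]])
        post = predict_nsc(model, test)
        assert post["predicted"].tolist() == ["lo", "hi"]

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(6)
        m = _em(rng.normal(size=(4, 30)))
        model = train_nsc(m, ["A"] * 18 + ["B"] * 12, delta_grid=[0.1])
        post = predict_nsc(model, _em(rng.normal(size=(4, 50))))
        np.testing.assert_allclose(post[["A", "B"]].sum(axis=1), 1.0, atol=1e-9)

    def test_missing_feature_listed(self):
        m = _em(np.random.default_rng(7).normal(size=(3, 10)),
                feature_ids=["a", "b", "c"])
        model = train_nsc(m, ["A"] * 5 + ["B"] * 5, delta_grid=[0.0])
        with pytest.raises(ValidationError, match="c"):
            predict_nsc(model, _em(m.values[:2], feature_ids=["a", "b"]))
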