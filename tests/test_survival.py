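import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank

from mirmaster.io import ValidationError
from mirmaster.simulate import SimulationConfig, simulate_cohort
from mirmaster.survival import (
    _breslow_loglik,
    cox_fit,
    km_estimate,
    logrank_test,
    stratify_by_mean,
)


class TestKaplanMeier:
    def test_three_events_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_flat(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert km.survival.size == 0  # curve stays at 1 throughout

    def test_subject_duplication_invariance(self):
        t, e = [2, 4, 4, 7], [1, 0, 1, 1]
        a = km_estimate(t, e)
        b = km_estimate(t * 2, e * 2)
        np.testing.assert_allclose(a.survival, b.survival, atol=1e-12)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        km = km_estimate(t, np.ones(40, dtype=int))
        for ti, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((t > ti).mean(), abs=1e-12)


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4.0] * 2
        e = [1, 1, 0, 1] * 2
        g = ["a"] * 4 + ["b"] * 4
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # A events at 1, 2; B events at 3, 4
        res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert res.observed["A"] == 2
        assert res.expected["A"] == pytest.approx(0.8333, abs=1e-4)
        assert res.chi_square == pytest.approx(2.882, abs=1e-3)

    def test_oe_balance_and_symmetry(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 60)
        e = (rng.random(60) < 0.7).astype(int)
        g = np.where(rng.random(60) < 0.5, "x", "y")
        res = logrank_test(t, e, g)
        total_o = sum(res.observed.values())
        total_e = sum(res.expected.values())
        assert total_o == pytest.approx(total_e, abs=1e-9)
        flipped = logrank_test(t, e, np.where(g == "x", "y", "x"))
        assert flipped.chi_square == pytest.approx(res.chi_square, abs=1e-9)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 80)
        e = (rng.random(80) < 0.7).astype(int)
        g = rng.random(80) < 0.4
        res = logrank_test(t, e, np.where(g, "a", "b"))
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert res.chi_square == pytest.approx(ref.test_statistic, abs=1e-8)
        assert res.p == pytest.approx(ref.p_value, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestStratifyByMean:
    def test_tie_at_mean_goes_low(self):
        assert stratify_by_mean([1, 2, 3]).tolist() == ["low", "low", "high"]

    def test_constant_all_low(self):
        assert set(stratify_by_mean([4, 4, 4, 4])) == {"low"}

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=25)
        assert stratify_by_mean(v).tolist() == stratify_by_mean(v + 11.5).tolist()


class TestCox:
    def test_six_subject_grid_search_oracle(self):
        """Newton fit equals brute-force maximization of the Breslow likelihood."""
        t = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
        e = np.array([1, 1, 1, 0, 1, 1])
        x = pd.DataFrame({"z": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0]})
        fit = cox_fit(t, e, x)
        grid = np.linspace(-5, 5, 200_001)
        xc = (x.to_numpy() - x.to_numpy().mean(axis=0))
        lls = [_breslow_loglik(np.array([b]), t, e, xc)[0] for b in grid]
        b_star = grid[int(np.argmax(lls))]
        assert fit.coef[0] == pytest.approx(b_star, abs=1e-4)

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(4)
        cover = 0
        for _ in range(10):
            t = rng.exponential(10, 300)
            e = (rng.random(300) < 0.8).astype(int)
            z = rng.normal(size=300)
            fit = cox_fit(t, e, pd.DataFrame({"z": z}))
            cover += fit.ci_lower[0] <= 1.0 <= fit.ci_upper[0]
        assert cover >= 8

    def test_matches_lifelines_multivariate(self):
        c = simulate_cohort(SimulationConfig(n_samples=400, seed=12))
        s = c.samples
        cov = pd.DataFrame({
            "mesenchymal": (s["subtype"] == "mesenchymal").astype(float).to_numpy(),
            "age": s["age"].to_numpy(dtype=float),
            "stage": s["stage"].to_numpy(dtype=float),
        })
        fit = cox_fit(s["time"].to_numpy(), s["event"].to_numpy(dtype=int), cov)
        df = cov.copy()
        df["T"], df["E"] = s["time"].to_numpy(), s["event"].to_numpy(dtype=int)
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, ref.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-5)
        assert fit.converged

    def test_planted_hazard_ratio_recovery(self):
        c = simulate_cohort(SimulationConfig(n_samples=2000, seed=8))
        s = c.samples
        cov = pd.DataFrame(
            {"mesenchymal": (s["subtype"] == "mesenchymal").astype(float).to_numpy()})
        fit = cox_fit(s["time"].to_numpy(), s["event"].to_numpy(dtype=int), cov)
        assert fit.hazard_ratio[0] == pytest.approx(2.0, rel=0.3)

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(8, 100)
        e = np.ones(100, dtype=int)
        fit = cox_fit(t, e, pd.DataFrame({"z": rng.normal(size=100)}))
        assert fit.ci_lower[0] <= fit.hazard_ratio[0] <= fit.ci_upper[0]

    def test_monotone_likelihood_flagged(self):
        # perfectly separating covariate: likelihood is monotone in beta
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.ones(6, dtype=int)
        fit = cox_fit(t, e, pd.DataFrame({"z": [1.0, 1, 1, 0, 0, 0]}))
        assert not fit.converged
        assert np.isnan(fit.hazard_ratio).all()

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            cox_fit([1, 2, 3], [1, 1, 0], pd.DataFrame({"z": [1.0, 1, 1]}))


def test_logrank_type_one_error_calibrated():
    """Two equal exponential groups with censoring: rejection rate near 0.05."""
    rng = np.random.default_rng(6)
    rejections = 0
    reps = 400
    for _ in range(reps):
        t = rng.exponential(10, 40)
        censor = rng.exponential(23, 40)  # ~30% censoring
        e = (t <= censor).astype(int)
        obs = np.minimum(t, censor)
        g = np.array(["a"] * 20 + ["b"] * 20)
        if e[:20].sum() == 0 or e[20:].sum() == 0:
            continue
        rejections += logrank_test(obs, e, g).p < 0.05
    assert 0.025 <= rejections / reps <= 0.075
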