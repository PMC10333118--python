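"""Synthetic-control estimator: predictor construction, the inner
simplex QP against a brute-force grid oracle, and fit invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tigersynth.errors import InsufficientDonorsError
from tigersynth.simulate import SimConfig, simulate_study
from tigersynth.synth import (
    PredictorMatrix,
    SynthConfig,
    build_predictors,
    fit_synthetic,
    inner_weights,
)

from conftest import make_toy_study
from oracles import grid_search_objective

SMALL = SynthConfig(allow_small_donor_pool=True)


def grid_best_objective(pm: PredictorMatrix, v: np.ndarray, step=0.005) -> float:
    return grid_search_objective(pm.x_treated, pm.x_donors, v, step)


def random_instance(rng, n_donors, k):
    return PredictorMatrix(
        predictor_names=[f"p{i}" for i in range(k)],
        x_treated=rng.normal(size=k),
        x_donors=rng.normal(size=(k, n_donors)),
        donor_ids=[f"D{j}" for j in range(n_donors)],
        center=np.zeros(k),
        scale=np.ones(k),
    )


class TestInnerWeights:
    def test_exact_match_donor_gets_all_weight(self):
        rng = np.random.default_rng(0)
        pm = random_instance(rng, 3, 4)
        pm.x_donors[:, 1] = pm.x_treated
        w, obj = inner_weights(pm, np.full(4, 0.25))
        assert obj < 1e-12
        assert w[1] == pytest.approx(1.0, abs=1e-6)

    def test_one_dim_convex_interpolation(self):
        # x_treated = 2 between donors at 1 and 4: w = (2/3, 1/3), objective 0
        pm = PredictorMatrix(["p"], np.array([2.0]), np.array([[1.0, 4.0]]),
                             ["A", "B"], np.zeros(1), np.ones(1))
        w, obj = inner_weights(pm, np.array([1.0]))
        assert obj == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-8)

    def test_matches_grid_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_donors = rng.integers(2, 4)  # grid stays exhaustive and fast
            k = rng.integers(1, 5)
            pm = random_instance(rng, int(n_donors), int(k))
            v = rng.dirichlet(np.ones(k))
            w, obj = inner_weights(pm, v)
            assert w.min() >= -1e-12 and w.sum() == pytest.approx(1.0, abs=1e-8)
            assert obj <= grid_best_objective(pm, v) + 1e-6

    def test_rejects_nonfinite(self):
        pm = PredictorMatrix(["p"], np.array([np.nan]), np.ones((1, 2)),
                             ["A", "B"], np.zeros(1), np.ones(1))
        with pytest.raises(FloatingPointError):
            inner_weights(pm, np.array([1.0]))


class TestBuildPredictors:
    def test_pre_loss_mean_and_standardisation(self):
        losses = {
            "R00": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
            "R01": [2, 4, 6, 8, 10, 12, 14, 16, 18, 20],
            "R02": [3, 6, 9, 12, 15, 18, 21, 24, 27, 30],
        }
        study = make_toy_study(n_reserves=3, losses=losses,
                               intervention={"R00": 2004})
        pm = build_predictors(study, "R00", ["R01", "R02"], 2004)
        i = pm.predictor_names.index("pre_loss_mean")
        # raw pre means over 2001-2003: 2, 4, 6 -> standardised with sd(ddof=1)=2
        raw = np.array([2.0, 4.0, 6.0])
        expect = (raw - raw.mean()) / raw.std(ddof=1)
        got = np.array([pm.x_treated[i], *pm.x_donors[i]])
        np.testing.assert_allclose(got, expect, atol=1e-12)
        # every kept predictor standardised: mean 0, variance 1 over pooled units
        pooled = np.hstack([pm.x_treated[:, None], pm.x_donors])
        np.testing.assert_allclose(pooled.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(pooled.var(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_constant_predictor_dropped_with_warning(self):
        study = make_toy_study(n_reserves=4, intervention={"R00": 2005})
        study.covariates["slope"] = 7.5
        with pytest.warns(UserWarning, match="slope"):
            pm = build_predictors(study, "R00", ["R01", "R02", "R03"], 2005)
        assert "slope" not in pm.predictor_names

    def test_too_few_donors(self):
        study = make_toy_study(n_reserves=2, intervention={"R00": 2005})
        with pytest.raises(InsufficientDonorsError):
            build_predictors(study, "R00", ["R01"], 2005)


class TestFitSynthetic:
    def test_clone_donor_gives_near_zero_pre_mspe_and_effect(self):
        base = [1, 3, 4, 7, 9, 12, 15, 16, 18, 22]
        losses = {"R00": base, "R01": list(base),
                  "R02": [2 * x for x in base], "R03": [3 * x for x in base]}
        study = make_toy_study(n_reserves=4, losses=losses,
                               intervention={"R00": 2006})
        fit = fit_synthetic(study, "R00", config=SMALL)
        assert fit.mspe_pre <= 1e-6
        np.testing.assert_allclose(fit.effect_series, 0.0, atol=1e-3)

    def test_two_donor_counterfactual_is_convex_interpolation(self):
        # 1-D outcome geometry: treated midway between two linear donors
        losses = {"R00": [2 * (t + 1) for t in range(10)],
                  "R01": [1 * (t + 1) for t in range(10)],
                  "R02": [4 * (t + 1) for t in range(10)]}
        study = make_toy_study(n_reserves=3, losses=losses,
                               intervention={"R00": 2006})
        fit = fit_synthetic(study, "R00", config=SMALL)
        expect = (2 / 3) * np.array(losses["R01"]) + (1 / 3) * np.array(losses["R02"])
        np.testing.assert_allclose(fit.counterfactual, expect, rtol=1e-5)

    def test_counterfactual_within_donor_envelope(self):
        study, _ = simulate_study(SimConfig(n_groups=1, donors_per_group=21,
                                            treated_per_group=1, seed=21))
        rid = study.treated_ids[0]
        fit = fit_synthetic(study, rid)
        wide = study.outcome_matrix(fit.donor_ids).to_numpy()
        assert (fit.counterfactual >= wide.min(axis=1) - 1e-6).all()
        assert (fit.counterfactual <= wide.max(axis=1) + 1e-6).all()

    def test_outer_search_never_worse_than_uniform_v(self):
        study, _ = simulate_study(SimConfig(n_groups=1, donors_per_group=21,
                                            treated_per_group=1, seed=33))
        rid = study.treated_ids[0]
        fit_uniform = fit_synthetic(study, rid, config=SynthConfig(outer_maxiter=0))
        fit_full = fit_synthetic(study, rid)
        assert fit_full.mspe_pre <= fit_uniform.mspe_pre + 1e-12

    @settings(max_examples=8)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_scale_equivariance(self, c):
        study, _ = simulate_study(SimConfig(n_groups=1, donors_per_group=21,
                                            treated_per_group=1, seed=5))
        rid = study.treated_ids[0]
        fit1 = fit_synthetic(study, rid)
        scaled = study.outcomes.copy()
        scaled["cumulative_loss_ha"] *= c
        from dataclasses import replace
        study_c = replace(study, outcomes=scaled)
        fit2 = fit_synthetic(study_c, rid)
        assert fit2.effect_final == pytest.approx(c * fit1.effect_final, rel=1e-6)
        assert fit2.mspe_pre == pytest.approx(c**2 * fit1.mspe_pre, rel=1e-6)
        assert fit2.mspe_post == pytest.approx(c**2 * fit1.mspe_post, rel=1e-6)

    def test_min_donor_rule(self):
        study = make_toy_study(n_reserves=5, intervention={"R00": 2006})
        with pytest.raises(InsufficientDonorsError, match="min_donors"):
            fit_synthetic(study, "R00")

    def test_weights_on_simplex_and_determinism(self):
        study, _ = simulate_study(SimConfig(n_groups=1, donors_per_group=25,
                                            treated_per_group=1, seed=8))
        rid = study.treated_ids[0]
        f1 = fit_synthetic(study, rid)
        f2 = fit_synthetic(study, rid)
        np.testing.assert_array_equal(f1.weights.w, f2.weights.w)
        np.testing.assert_array_equal(f1.weights.v, f2.weights.v)
        assert f1.weights.w.min() >= -1e-12
        assert f1.weights.w.sum() == pytest.approx(1.0, abs=1e-8)
        assert f1.weights.v.sum() == pytest.approx(1.0, abs=1e-8)
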